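gene	drug	approval_note
ERBB2	trastuzumab	synthetic demo catalog; replace with a full FDA-approved target table
ERBB2	pertuzumab	synthetic demo catalog
EGFR	cetuximab	synthetic demo catalog
TACSTD2	sacituzumab govitecan	synthetic demo catalog
CD44	RG7356	synthetic demo catalog (investigational)
MUC1	gatipotuzumab	synthetic demo catalog (investigational)
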