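gene	provenance
ERBB2	synthetic demo surfaceome; replace with a full surfaceome list
EGFR	synthetic demo surfaceome
EPCAM	synthetic demo surfaceome
CD44	synthetic demo surfaceome
MUC1	synthetic demo surfaceome
ITGB1	synthetic demo surfaceome
FGFR4	synthetic demo surfaceome
TACSTD2	synthetic demo surfaceome
CXCR4	synthetic demo surfaceome
IL6R	synthetic demo surfaceome
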