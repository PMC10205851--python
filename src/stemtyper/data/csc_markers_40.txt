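# 40-marker cancer-stem-cell vignette for sum scoring (editable).
# Curated from published breast CSC marker literature.
CD44
CD24
ALDH1A1
ALDH1A3
PROM1
EPCAM
ITGA6
ITGB1
ITGB3
THY1
KIT
CXCR4
ABCG2
ABCB1
SOX2
POU5F1
NANOG
KLF4
MYC
BMI1
NOTCH1
JAG1
DLL1
GLI1
GLI2
WNT5A
CTNNB1
LGR5
SNAI1
SNAI2
TWIST1
ZEB1
ZEB2
VIM
CDH2
STAT3
IL6R
EGFR
ERBB2
MUC1
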