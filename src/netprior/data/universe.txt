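# Analysis universe: the inhibited target plus its known downstream genes.
MMP12
ACTR3
ADAM9
AEBP1
APOA1
APOL1
ARPC1B
ATIC
CAPZA1
CAPZA2
CCL1
CCL14
CCL15
CCL16
CCL23
CD44
COL1A1
COL3A1
COL4A1
CORO1C
CR1
CXCL1
CXCL13
CXCL5
CXCL8
EFEMP1
EFEMP2
ELN
F12
FASLG
FBLN5
FN1
LAMA1
MBP
MMP2
MMP3
NFKBIA
NID
PLAUR
POSTN
PPBP
PSME3
SERPINA10
SERPINB1
SPARCL1
SPP1
TFPI
THBS2
TNC
TNF
VTN
YARS1
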