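# Therapeutic expectation for each panel gene under target inhibition.
# "adaptive" marks the compensatory axis (upregulation expected as escape);
# "variable" marks compound-specific regulation with no single expected sign.
gene	expected
MMP12	Dn
NFKBIA	Up
CD44	Dn
CCL15	Dn
PSME3	Dn
SPARCL1	Dn
ADAM9	adaptive
APOA1	variable
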