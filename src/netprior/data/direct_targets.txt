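# Direct (one-step shortest-path) targets of MMP12 per the prioritization table.
CD44
MMP2
NFKBIA
PSME3
SPARCL1
TNF
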