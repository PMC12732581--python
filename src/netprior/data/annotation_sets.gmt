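# SYNTHETIC stand-in for the four proprietary cancer-process gene sets
# (lung cancer pathogenesis, apoptosis regulation, cell migration, expressed
# in A549).  Constructed so that each prioritized gene's membership count
# equals its printed overlap value; decoy members pad each set.
LUNG_CANCER_PATHOGENESIS	disease	ACTR3	ADAM9	APOA1	ARPC1B	ATIC	CAPZA1	CAPZA2	CCL1	CCL14	CCL15	CCL16	CCL23	CD44	CORO1C	CXCL13	NFKBIA	PPBP	PSME3	SPARCL1	EGFR	KRAS	TP53
APOPTOSIS_REGULATION	process	ACTR3	ADAM9	APOA1	ARPC1B	ATIC	CAPZA1	CAPZA2	CCL1	CCL14	CCL15	CCL16	CCL23	CD44	CORO1C	CXCL13	NFKBIA	PPBP	BCL2	CASP3	BAX
CELL_MIGRATION	process	ADAM9	APOA1	CCL14	CCL15	CD44	SNAI1	VIM	CDH2
A549_EXPRESSED	cell-line	GAPDH	ACTB	B2M
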