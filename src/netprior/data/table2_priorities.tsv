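# Reference prioritization table (21 printed rows; score-0 genes unlisted).
Gene	Direct Effect	Transcriptional Effect	OverlappingGene	Total Score
CD44	1	0	3	4
NFKBIA	1	1	2	4
PSME3	1	1	1	3
SPARCL1	1	1	1	3
ADAM9	0	0	3	3
APOA1	0	0	3	3
CCL14	0	0	3	3
CCL15	0	0	3	3
ACTR3	0	0	2	2
ARPC1B	0	0	2	2
ATIC	0	0	2	2
CAPZA1	0	0	2	2
CAPZA2	0	0	2	2
CCL1	0	0	2	2
CCL16	0	0	2	2
CCL23	0	0	2	2
CORO1C	0	0	2	2
CXCL13	0	0	2	2
PPBP	0	0	2	2
MMP2	1	0	0	1
TNF	1	0	0	1
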