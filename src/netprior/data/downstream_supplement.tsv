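# Downstream genes that appear in the prioritization table but not among the
# 40 printed interaction rows (they belong to the unpublished full inventory
# of 113 outgoing targets).  Effect/mechanism are unspecified for these.
Downstream Network Object	GeneSymbol	Effect	Mechanism
CD44	CD44	Unspecified	Unspecified
ADAM9	ADAM9	Unspecified	Unspecified
CCL14	CCL14	Unspecified	Unspecified
ACTR3	ACTR3	Unspecified	Unspecified
ARPC1B	ARPC1B	Unspecified	Unspecified
ATIC	ATIC	Unspecified	Unspecified
CAPZA1	CAPZA1	Unspecified	Unspecified
CAPZA2	CAPZA2	Unspecified	Unspecified
CCL1	CCL1	Unspecified	Unspecified
CORO1C	CORO1C	Unspecified	Unspecified
PPBP	PPBP	Unspecified	Unspecified
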