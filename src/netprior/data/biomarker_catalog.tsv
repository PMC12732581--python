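# SYNTHETIC biomarker catalog fixture: three panel genes carry established
# cancer biomarker roles in the lung-cancer cell-line context; decoy rows
# exercise the species/disease/context filters.
gene	species	disease	context	biomarker_roles
ADAM9	Homo sapiens	cancer	lung cancer cell lines	efficacy;prognosis
CD44	Homo sapiens	cancer	lung cancer cell lines	diagnosis;progression;prognosis
MMP12	Homo sapiens	cancer	lung cancer cell lines	efficacy
NFKBIA	Homo sapiens	inflammation	lung cancer cell lines	response
CD44	Mus musculus	cancer	lung cancer cell lines	prognosis
SPARCL1	Homo sapiens	cancer	breast cancer cell lines	prognosis
EGFR	Homo sapiens	cancer	lung cancer cell lines	diagnosis
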