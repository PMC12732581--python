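# Reference upstream-regulator calls (20 regulators; TXN prints two z values
# for two compound subsets, hence 21 numeric rows).  "targets" records the
# observed direction arrows; n_consistent is the consistency split implied by
# z = (n_consistent - n_inconsistent)/sqrt(n_used).  split_forced marks rows
# where |z| = sqrt(n) or z = 0 pins the split exactly; the rest are derived.
regulator	category	targets	z	z_compounds	compounds	n_used	n_consistent	split_forced
MMP12	peptidase	NFKBIA:+1,PSME3:-1,SPARCL1:-1	+1.73	C1,C7,C9,C10,C15	C1,C7,C9,C10,C15	3	3	1
TXN	enzyme	APOA1:-1,CD44:-1,MMP12:-1,NFKBIA:+1	+2.00	C1,C10	C1,C7,C10,C15	4	4	1
TXN	enzyme	APOA1:+1,CD44:-1,MMP12:-1,NFKBIA:+1	+1.00	C7,C15	C1,C7,C10,C15	4	3	0
ITCH	enzyme	ADAM9:+1,CD44:-1,MMP12:-1,NFKBIA:+1	-1.00	C1,C7,C10,C15	C1,C7,C10,C15	4	1	0
AKT family	kinase	CD44:-1,MMP12:-1,NFKBIA:+1	-1.73	C1,C7,C10,C15	C1,C7,C10,C15	3	0	1
MAP3K11	kinase	CD44:-1,MMP12:-1,NFKBIA:+1,PSME3:-1	-1.00	C1,C7,C10,C15	C1,C7,C10,C15	4	1	0
MAP2K7	kinase	CD44:-1,MMP12:-1,NFKBIA:+1	-0.58	C1,C7,C10,C15	C1,C7,C10,C15	3	1	0
MAP3K14	kinase	CD44:-1,NFKBIA:+1	0.00	C1,C7,C10,C15	C1,C7,C10,C15	2	1	1
ECSIT	other	CD44:-1,NFKBIA:+1	0.00	C7,C10,C15	C7,C10,C15	2	1	1
DGKH	kinase	CD44:-1,MMP12:-1,NFKBIA:+1	-0.58	C1,C7,C10,C15	C1,C7,C10,C15	3	1	0
SH3RF1	enzyme	CD44:-1,MMP12:-1,NFKBIA:+1	-0.58	C1,C7,C10,C15	C1,C7,C10,C15	3	1	0
VEGFA	growth factor	CD44:-1,MMP12:-1	-1.41	C1	C1	2	0	1
CRK/CRKL	group	APOA1:+1,CCL15:-1,CD44:-1,MMP12:-1,NFKBIA:+1	-2.24	C9	C9	5	0	1
SMAD2/3/4 complex	complex	ADAM9:+1,APOA1:+1,CD44:-1,MMP12:-1,NFKBIA:+1	+0.45	C9	C9	5	3	0
EIF3H	translation regulator	ADAM9:+1,CD44:-1,MMP12:-1,NFKBIA:+1,PSME3:-1	+1.34	C9	C9	5	4	0
NRG4	growth factor	ADAM9:+1,APOA1:+1,CD44:-1,MMP12:-1,NFKBIA:+1,SPARCL1:-1	-0.82	C9	C9	6	2	0
ERBB family	kinase	ADAM9:+1,APOA1:+1,CD44:-1,MMP12:-1,NFKBIA:+1,SPARCL1:-1	-0.82	C9	C9	6	2	0
RHO-GDI	group	ADAM9:+1,APOA1:+1,CD44:-1,MMP12:-1,NFKBIA:+1	-1.34	C9	C9	5	1	0
EGFR	kinase	ADAM9:+1,APOA1:+1,CD44:-1,MMP12:-1,NFKBIA:+1,SPARCL1:-1	-0.82	C9	C9	6	2	0
BHLH	transcription regulator	APOA1:+1,CD44:-1,MMP12:-1,NFKBIA:+1,SPARCL1:-1	-0.45	C9	C9	5	2	0
ERBB4/APOE complex	complex	ADAM9:+1,APOA1:+1,CD44:-1,SPARCL1:-1	+1.00	C9	C9	4	3	0
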