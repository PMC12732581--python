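# qPCR fold changes of the eight-gene panel under five inhibitors (printed
# percent/direction cells kept verbatim; one cell is internally inconsistent
# and is flagged by validation, never corrected).
Compound	Gene	Fold Change	% Change	Direction
C1	CD44	0.48	-52%	Dn
C1	NFKBIA	24.33	+2333%	Up
C1	PSME3	0.54	-46%	Dn
C1	SPARCL1	0.49	-51%	Dn
C1	ADAM9	123.60	+12,260%	Up
C1	APOA1	0.79	-21%	Dn
C1	CCL15	0.03	-97%	Dn
C1	MMP12	0.78	-22%	Dn
C7	CD44	0.23	-77%	Dn
C7	NFKBIA	25.19	+2419%	Up
C7	PSME3	0.66	-34%	Dn
C7	SPARCL1	0.56	-44%	Dn
C7	ADAM9	29.45	+28.45	Up
C7	APOA1	12.17	+1117	Up
C7	CCL15	0.05	-95%	Dn
C7	MMP12	0.15	-85%	Dn
C9	CD44	0.91	-9%	Dn
C9	NFKBIA	29.10	+2810%	Up
C9	PSME3	0.36	-64%	Dn
C9	SPARCL1	0.34	-66%	Dn
C9	ADAM9	111.04	+11,004%	Up
C9	APOA1	7.67	+667%	Up
C9	CCL15	0.05	-95%	Dn
C9	MMP12	0.23	-77%	Dn
C10	CD44	0.45	-55%	Dn
C10	NFKBIA	18.50	+1750%	Up
C10	PSME3	0.97	-3%	Dn
C10	SPARCL1	0.26	-74%	Dn
C10	ADAM9	267.80	+26,680%	Up
C10	APOA1	0.81	-19%	Dn
C10	CCL15	0.05	-95%	Dn
C10	MMP12	0.57	-43%	Dn
C15	CD44	0.68	-32%	Dn
C15	NFKBIA	28.34	+2734%	Up
C15	PSME3	0.52	-48%	Dn
C15	SPARCL1	0.79	-21%	Dn
C15	ADAM9	39.26	+3826%	Up
C15	APOA1	6.34	+534%	Up
C15	CCL15	0.03	-97%	Dn
C15	MMP12	0.20	-80%	Dn
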