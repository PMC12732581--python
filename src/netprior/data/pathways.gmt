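# Toy canonical-pathway collection: each set carries the published enriched
# genes for the eight-gene panel plus SYNTHETIC filler members (the source
# knowledge base is proprietary, so FDR values computed over this toy
# collection are illustrative, not reference values).  The chemokine set is a
# synthetic supplement covering CCL15.
HOTAIR regulatory pathway	pathway	CD44	MMP12	NFKBIA	HOXD10	EZH2	SUZ12
Role of Osteoclasts in rheumatoid arthritis	pathway	MMP12	ADAM9	NFKBIA	TNFSF11	ACP5	CTSK
Collagen degradation	pathway	MMP12	ADAM9	MMP1	MMP8	COL1A2
Degradation of the extracellular matrix	pathway	CD44	MMP12	MMP9	TIMP1	LAMB1
ABC-family protein-mediated transport	pathway	PSME3	APOA1	ABCA1	ABCB1	ABCG1
Post-translational protein phosphorylation	pathway	APOA1	SPARCL1	FAM20C	F2	AHSG
Regulation of IGF transport and uptake by IGFBPs	pathway	APOA1	SPARCL1	IGF1	IGFBP3	IGFBP5
TCR signaling	pathway	NFKBIA	PSME3	LCK	ZAP70	CD3E
Interleukin-1 family signaling	pathway	NFKBIA	PSME3	IL1B	IL1R1	MYD88
Centrosomal KIAA0586 signaling pathway	pathway	CD44	PSME3	KIAA0586	PLK4	CEP152
Chemokine signaling	pathway-synthetic	CCL15	CCL16	CCL23	CCL1	CCL14	CXCL13	PPBP	CCR1
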