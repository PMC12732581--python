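# Curated downstream (outgoing) interactions of MMP12: 40 printed rows.
Downstream Network Object	GeneSymbol	Effect	Mechanism
C3b	CR1	Activation	Cleavage
CCL15	CCL15	Activation	Cleavage
CCL16	CCL16	Activation	Cleavage
CCL23	CCL23	Activation	Cleavage
MMP-2	MMP2	Activation	Cleavage
NFKBIA	NFKBIA	Activation	Transcription regulation
Osteopontin	SPP1	Activation	Cleavage
Stromelysin-1(MMP-3)	MMP3	Activation	Unspecified
TNF-alpha	TNF	Activation	Cleavage
TyrRS	YARS1	Activation	Cleavage
AEBP1	AEBP1	Inhibition	Cleavage
Alpha 1-antitrypsin	SERPINA10	Inhibition	Cleavage
APOA1	APOA1	Inhibition	Cleavage
APOL1	APOL1	Inhibition	Cleavage
Coagulation factor XII	F12	Inhibition	Cleavage
Collagen I	COL1A1	Inhibition	Cleavage
Collagen III	COL3A1	Inhibition	Cleavage
Collagen IV	COL4A1	Inhibition	Cleavage
CXCL13	CXCL13	Inhibition	Cleavage
EFEMP2	EFEMP2	Inhibition	Cleavage
Elastin	ELN	Inhibition	Cleavage
ENA-78	CXCL5	Inhibition	Cleavage
FasL(TNFSF6)	FASLG	Inhibition	Cleavage
Fibronectin	FN1	Inhibition	Cleavage
Fibulin-3	EFEMP1	Inhibition	Cleavage
Fibulin-5	FBLN5	Inhibition	Cleavage
GRO-1	CXCL1	Inhibition	Cleavage
IL-8	CXCL8	Inhibition	Cleavage
Laminin 1	LAMA1	Inhibition	Cleavage
Myelin basic protein	MBP	Inhibition	Cleavage
Nidogen	NID	Inhibition	Cleavage
OSF-2	POSTN	Inhibition	Cleavage
PLAUR	PLAUR	Inhibition	Cleavage
PSME3	PSME3	Inhibition	Transcription regulation
SERPINB1	SERPINB1	Inhibition	Cleavage
SPARCL1	SPARCL1	Inhibition	Transcription regulation
Tenascin-C	TNC	Inhibition	Cleavage
TFPI	TFPI	Inhibition	Cleavage
Thrombospondin 2	THBS2	Inhibition	Cleavage
Vitronectin	VTN	Inhibition	Cleavage
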