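GIN20	20-gene genomic-instability signature (dual-cohort FGA correlation, r>=0.35)	APMAP	CDK4	CECR5	CNNM1	DLX6	FLVCR1	GLI2	GTPBP3	MTA1	PEX5	PMS2P1	PNCK	SLC30A3	SMYD3	TFB2M	TMEM161A	TMEM97	USP39	VMA21	ZNF74
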