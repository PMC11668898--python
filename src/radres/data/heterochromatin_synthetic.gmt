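HETEROCHROMATIN_FORMATION_SYN	synthetic 91-gene stand-in for the heterochromatin formation pathway; supply your own GMT for real analyses	BAHD1	CBX1	CBX3	CBX5	EZH1	EZH2	SUZ12	EED	RBBP4	RBBP7	SUV39H1	SUV39H2	SETDB1	SETDB2	EHMT1	EHMT2	TRIM28	ATRX	DAXX	MECP2	HDAC1	HDAC2	SIRT1	SIRT6	DNMT1	DNMT3A	DNMT3B	UHRF1	MBD1	MBD2	SMCHD1	MORC2	MORC3	MPHOSPH8	TASOR	PPHLN1	FAM208B	SAFB	SAFB2	SLTM	LBR	LMNB1	LMNB2	LMNA	PRR14	CBX2	CBX4	CBX6	CBX7	CBX8	RING1	RNF2	PCGF1	PCGF2	PCGF6	PHC1	PHC2	PHC3	SCMH1	BMI1	HELLS	CDCA7	ZBTB24	TRIM66	SMARCAD1	NAP1L1	CHAF1A	CHAF1B	ASF1A	ASF1B	HIRA	UBN1	CABIN1	HMGA1	HMGA2	HP1BP3	BAZ1A	BAZ1B	BAZ2A	BAZ2B	TTF1	SIRT7	NCL	NPM1	KDM2A	RSF1	SMARCA5	BAHCC1	L3MBTL1	L3MBTL2	SGO1
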