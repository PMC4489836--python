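# 19-SNP coronary heart disease gene-score panel.
# Per-allele odds ratios from the published meta-analyses cited for each variant;
# weights are computed at load time as ln(odds_ratio), never stored here.
# model: additive (contribution = dosage x weight) or recessive (weight only for
# two risk alleles; applies to NOS3 rs1799983 alone).
# in_13_panel marks the GWAS-consortium subset used for the 13-SNP score.
# rs599839 is the canonical rsid for the SORT1 locus (genotyped as a proxy for
# rs646776, r2 = 0.95 in Europeans); rs646776 is accepted as an input alias.
# rs7412 (APOE) is scored on the protective T allele, odds ratio 0.80, so its
# weight is negative.
rsid	locus	risk_allele	odds_ratio	model	in_13_panel	note
rs17465637	MIA3	C	1.14	additive	true
rs10757274	9p21	G	1.29	additive	true
rs7025486	DAB2IP	A	1.16	additive	false
rs1746048	CXCL12	C	1.17	additive	true
rs4341	ACE	G	1.22	additive	false	indel proxy, scored as biallelic SNP
rs1799983	NOS3	T	1.31	recessive	false	recessive model
rs662799	APOA5	G	1.19	additive	true	promoter variant
rs17228212	SMAD3	C	1.21	additive	false
rs1042031	APOB	A	1.73	additive	true
rs708272	CETP	C	1.28	additive	false
rs3798220	LPA	C	1.92	additive	true
rs10455872	LPA	G	1.70	additive	true
rs9818870	MRAS	T	1.15	additive	true
rs328	LPL	C	1.25	additive	true
rs1801177	LPL	A	1.33	additive	false
rs599839	SORT1	A	1.19	additive	true	proxy for rs646776
rs11591147	PCSK9	G	1.43	additive	true
rs429358	APOE	C	1.06	additive	true
rs7412	APOE	T	0.80	additive	true	protective allele scored
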