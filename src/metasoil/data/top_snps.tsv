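snp	gene	chrom	snprank_score	location	maf
rs11139965	RN7SKP242	9	0.5898	intergenic	0.170
rs67242866	LINC01362	1	0.5784	intergenic	0.028
rs199830092	PIK3C2B	1	0.5749	intron_variant	NA
rs72951131	ZAP70	2	0.5587	intron_variant	0.183
rs34000182	MIR5689HG	6	0.5485	intron_variant	0.053
rs61776380	RNU6-830P	1	0.5444	intergenic	0.065
rs778902	ISCA1P2	1	0.5378	intergenic	0.098
rs2501357	C1orf204	1	0.5360	intron_variant	0.306
rs742635	ABTB2	11	0.5349	intron_variant	0.085
rs16927008	CLVS1	8	0.5324	intron_variant	0.027
rs4849127	IL1B	2	0.5257	downstream_gene_variant	0.125
rs41263676	C1orf21	1	0.5251	3_prime_UTR_variant	0.131
rs11692741	MYT1L	2	0.5211	intron_variant	0.180
rs77142354	MIR4300HG	11	0.5165	intron_variant	0.039
rs77162747	ZNF767P	7	0.5144	intergenic	0.072
rs77169575	MAML3	4	0.5142	intron_variant	0.198
rs9994379	ELOVL6	4	0.5136	intron_variant	0.034
rs13421497	PRKCE	2	0.5134	intergenic	0.073
rs1197934	LINGO2	9	0.5128	intron_variant	0.112
rs75394800	EML6	2	0.5115	intron_variant	0.033
rs3799142	VIP	6	0.5039	downstream_gene_variant	0.172
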