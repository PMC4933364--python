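locus	index_snp	variant_id	mean_imputation_r2	r2_with_index	predicted_gene	location	n_open_chromatin_cell_lines	open_in_crc_cell_line	n_histone_cancer_cell_lines	n_histone_normal_cell_lines	n_histone_colorectal_tissues	proteins_bound	binding_in_crc_cell_line	motif_altered	conserved
5q31.1	rs647161	rs1366111	0.89	0.57	PITX1	intronic	2	0	2	0	2	POL2;EGR1	0	1	0
8q24	rs6983267	rs6983267	0.95	index	MYC	intergenic	1	1	1	2	1	TCF4;P300;FOXA1;RXRA;SP1	1	1	1
11q13.4	rs3824999	rs3824999	0.99	index	POLD3	intronic	4	0	0	2	1	JUND	0	1	0
11q23	rs3802842	rs7130173	0.95	0.93	unknown	intronic	31	1	0	0	2	RAD21;SMC3;YY1;CTCF	0	1	0
12p13.32	rs3217901	rs3217827	0.85	0.61	CCND2	intronic	1	0	0	0	1	RAD21;CTCF	0	0	0
12q24.21	rs59336	rs71807	0.89	0.86	TBX3	intergenic	1	0	2	4	2	BAF155;HAE2F1;CTCF	0	0	0
12q24.21	rs59336	rs484443	0.91	0.90	TBX3	intronic	8	0	1	2	2	P300;USF1	0	1	0
14q22.2	rs4444235	rs2071047	1.00	0.75	BMP4	intronic	9	0	3	3	4	TCF4	1	1	0
14q22.2	rs4444235	rs10130587	0.74	0.67	BMP4	intronic	2	0	3	3	4	GATA3	0	1	0
14q22.2	rs4444235	rs35107139	0.82	0.64	BMP4	intronic	2	0	3	3	3	GATA3	0	1	0
15q13	rs4779584	rs2293582	0.94	0.71	GREM1	intronic	4	0	3	5	4	POL2	0	0	0
15q13	rs4779584	rs2293581	0.97	0.66	GREM1	intronic	36	0	4	5	4	SUZ12	0	0	0
15q13	rs4779584	rs1406389	0.97	0.66	GREM1	intergenic	12	0	3	4	3	SUZ12	0	1	0
18q21	rs4939827	rs11874392	0.93	1.00	SMAD7	intronic	4	0	3	1	3	11 proteins	0	0	1
18q21	rs4939827	rs4939567	0.91	1.00	SMAD7	intronic	1	0	4	3	4	MAFK	0	1	1
18q21	rs4939827	rs34007497	0.91	0.57	SMAD7	intronic	22	0	2	4	4	CTCF;STAT1	0	1	0
19q13.1	rs10411210	rs10411210	0.94	index	RHPN2	intronic	48	1	2	1	2	17 proteins	0	1	1
20p12.3	rs961253	rs966817	1.00	0.87	BMP2	intergenic	18	0	0	1	0	CJUN	0	1	1
20p12.3	rs4813802	rs4813802	0.86	index	BMP2	intergenic	10	0	2	2	1	6 proteins	0	0	1
20p12.3	rs4813802	rs6085661	0.89	0.76	BMP2	intergenic	19	0	1	0	1	7 proteins	0	1	1
20q13.33	rs4925386	rs1741634	0.96	0.80	LAMA5	intronic	7	0	0	2	2	GR	0	1	0
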