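locus	index_snp	n_snps_region	top_snp	top_snp_pos	r2_with_index
1q25.3	rs10911251	1886	rs6669796	183082825	0.87
1q41	rs6687758	1885	rs143030473	222161943	<0.2
1q41	rs6691170	2096	rs143030473	222161943	<0.2
2q32.3	rs11903757	1536	rs6731095	192589442	1.00
3q26.2	rs10936599	1651	rs2421771	169411370	<0.2
5q31.1	rs647161	1499	rs2193941	134469594	0.57
6p21	rs1321311	2364	rs13215272	36589502	<0.2
8q23.3	rs16892766	1432	rs16888589	117635602	0.92
8q24	rs6983267	2257	rs7013278	128414892	0.40
9p24	rs719725	1907	rs7875812	6364533	1.00
10p14	rs10795668	2363	rs1537603	8734295	0.45
11q13.4	rs3824999	1788	rs72977282	74300441	0.59
11q23	rs3802842	1830	rs7130173	111154072	0.95
12p13.32	rs10774214	1656	rs3217874	4400808	<0.2
12p13.32	rs3217810	1571	rs3217874	4400808	<0.2
12p13.32	rs3217901	1539	rs3217874	4400808	0.65
12q13.13	rs11169552	1310	rs7306677	51205763	<0.2
12q13.13	rs7136702	967	rs11169524	51089734	0.67
12q24.21	rs59336	2072	rs1427760	115100714	0.71
14q22.2	rs1957636	1613	rs10130587	54419110	<0.2
14q22.2	rs4444235	1659	rs10130587	54419110	0.67
15q13	rs11632715	1735	rs2293582	33010412	0.23
15q13	rs16969681	1692	rs2293582	33010412	0.22
15q13	rs4779584	1701	rs2293582	33010412	0.71
16q22.1	rs9929218	1867	rs9932005	68822019	0.63
18q21	rs4939827	1931	rs2337113	46452327	0.91
19q13.1	rs10411210	2307	rs75414102	33302424	<0.2
20p12.3	rs2423279	1901	rs118184022	7719449	<0.2
20p12.3	rs4813802	1825	rs6085662	6698372	1.00
20p12.3	rs961253	1990	rs56083061	6430696	0.28
20q13.33	rs4925386	2173	rs1760073	60926106	0.81
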