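population	chrom	start_bp	end_bp	mean_ancestry	n_genes_canine	n_genes_human	n_snps	n_cai_genes	n_cai_snps
wolf	1	118527129	118918741	0.094	3	3	26	0	0
wolf	2	3579904	7247465	0.121	8	13	44	2	2
wolf	2	21701739	22475191	0.110	6	6	33	1	1
wolf	3	9217526	9862481	0.118	1	1	36	0	0
wolf	4	7674062	8250087	0.089	7	8	30	0	0
wolf	8	27548538	28277904	0.083	4	4	24	0	0
wolf	13	28216740	28398676	0.093	1	1	13	0	0
wolf	14	27898988	28678482	0.095	1	1	40	0	0
wolf	19	52067458	52340491	0.093	1	3	21	0	0
wolf	23	43608851	44248615	0.098	9	9	41	0	0
wolf	26	34215853	34425449	0.078	1	1	16	0	0
wolf	28	20956513	21517197	0.080	2	2	37	0	0
wolf	30	29515850	29677034	0.087	2	2	10	0	0
wolf	34	35623963	37106724	0.131	8	9	83	1	1
wolf	35	8750539	10496444	0.100	5	7	109	0	0
wolf	37	30592158	30874615	0.091	2	2	17	0	0
frd	1	60419833	62667942	0.073	8	8	95	6	9
frd	2	35398496	37126070	0.058	42	43	54	3	4
frd	3	418639	2094780	0.072	8	8	57	1	1
frd	3	85336069	85680942	0.064	3	3	23	0	0
frd	4	43598	3426340	0.181	12	13	133	2	8
frd	5	1559873	3379769	0.127	2	2	97	2	4
frd	7	62475370	62647106	0.056	1	1	10	0	0
frd	9	779889	2719467	0.162	30	30	76	10	20
frd	13	2213820	2419264	0.055	1	1	10	0	0
frd	14	2529729	4675587	0.154	14	14	99	4	10
frd	17	51048	3686421	0.138	17	18	150	8	11
frd	20	144948	3406396	0.164	32	38	72	3	3
frd	22	108262	4593585	0.315	32	32	196	16	19
frd	23	33728739	34485710	0.059	7	7	42	0	0
frd	25	151268	4644607	0.070	24	25	129	8	26
frd	27	44109742	44912153	0.062	8	8	60	1	14
frd	28	488365	2383854	0.101	22	24	84	6	12
frd	30	1366	1819062	0.073	21	26	70	5	9
frd	32	16465021	17467739	0.062	6	6	60	1	1
frd	34	127067	2342162	0.104	4	4	115	2	10
frd	36	28437436	28698900	0.071	0	0	22	0	0
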