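name	mirna_seq	contig	length	strand	position	star_seq	leaf	root	flower	fruit	total
miRC1	ACAGGGAAGAGGTAGAGCATG	MDC006505.260	21	-	3797	ATGCACTGCCTCTTCCCTGGC	1091	23246	0	12	24349
miRC2	ACCTAGCTCTGATACCATGAA	MDC018599.370	21	+	9369	TGTGGTATCAGGACTATGTTA	893	261	5364	1823	8341
miRC3	CTACCGATGCCACTAAGTCCCA	MDC017130.228	22	+	6809	GGACTTAGTAGCTCGGTGA	266	247	1567	671	2751
miRC4	TGTTATATTGTCAGATTGTCA	MDC019554.272	21	-	10154	ACAGTCTGACAATATAACGTG	1035	502	6	0	1543
miRC5	AATGGAAGGGTAGGAAAGAAG	MDC006350.123	21	-	2997	TCTTTCCTATCCCTCCCATTCC	1021	324	144	0	1490
miRC6a	TCCTCTTGGTGATCGCCCTGT	MDC009272.709	21	-	4184	AGGGTGATTAACAAAGGGATG	359	279	336	319	1294
miRC6b	TCCTCTTGGTGATCGCCCTGC	MDC006081.961	21	-	466	AGGGTGGTTACCAATGGGATG	122	218	0	46	385
miRC7	TTATACAGAGAAATCACGGTCG	MDC009778.59	22	-	4735	ACCGTGTTTTTCTGTATAAAG	511	624	108	27	1270
miRC8	AAGAGCGGGATGTGTAAAAGG	MDC001018.301	21	+	2490	CTTTTACCTATCCCATTCTGT	248	0	0	0	248
miRC9	TCTGTCGTGGGTGAGATGGTGC	MDC011178.406	22	-	16699	TTCATCTCTCCTCGACAGAAG	137	90	0	4	231
miRC10	GAATTCCTTCTCCTCTCCTTT	MDC026449.10	21	-	340	AGGAGGGAGAGAGGGTTTTAC	0	0	166	7	173
miRC11	CACCAATATCAACTTTATTTG	MDC005581.168	21	+	2657	AATAAAGTTGATATTGGTGTG	6	12	44	38	100
miRC12	TCTGTCGAAGGTGAGATGGTGC	MDC003092.251	22	+	8878	TTCATCCCTCCTCGACTGAAG	10	64	0	0	73
miRC13	ATCCAACGAAGCAGGAGCTGA	MDC009318.175	21	+	3804	AGCTGCTGACTCGTTGGTTCA	0	0	18	42	60
miRC14	CGAACTTATTGCAACTAGCTT	MDC008558.180	21	+	6507	CAAGCTAGTTGTAATAAGTTC	24	0	13	0	38
miRC15	AAAGTATCAAGGAGCGCAAAG	MDC014075.204	21	-	26060	TTGCGTTCCACTGATTCTTTCG	8	8	9	2	27
miRC16	CATCTGGGTCGTTCAAATTTA	MDC009589.307	21	-	1975	AATTTGAACGGCCCAGATGGG	10	12	0	0	22
miRC17	ATCATGCGATCCCTTCGGACG	MDC005391.194	21	+	11429	TCCAAAGGGATCGCATTGATCT	11	0	0	0	11
miRC18	ATACTCATCGAATTTGTCATA	MDC012422.128	21	+	849	TGACAAATTGGATGAGTATTC	3	0	4	0	8
miRC19	TGGGATGTTGGTATGGTTCAA	MDC016463.170	21	-	5187	GAGCCGTGCCAATATCACAGT	0	7	0	0	7
miRC20	TGAAGAGAAGAGCGTTGTTTGG	MDC001494.456	22	-	33010	TGACAGCCTCTTCTTCTCATG	6	0	0	0	6
miRC21	ATCATTAACACTTAATAACGA	MDC006081.432	21	+	219	TTATTAAGTGTTAATGATTGG	0	0	0	2	2
miRC22	CCATATGTCCCTCCATATACT	MDC016302.308	21	+	5368	No star found	0	0	72	8	80
miRC23	AATGATGATCAAACAACCCTT	MDC020884.221	21	+	4086	No star found	0	0	46	2	48
miRC24	TGAACTTGGCTGAATGTGGACT	MDC001394.253	22	-	378	No star found	22	19	0	0	40
miRC25	TTTCGGAACCACTTACACCCA	MDC017130.228	21	+	9764	No star found	0	0	24	0	24
miRC26	TCCCCAAAACCCCTCATTCCAA	MDC017130.228	22	+	9967	No star found	0	0	15	0	15
miRC27	TTGCCAAAGGAGATCTGCTCAG	MDC019485.283	22	-	7997	No star found	6	0	0	6	12
miRC28	TGCATTTGCACCTGCACTTGT	MDC007946.169	21	-	672	No star found	0	0	9	3	11
miRC29	CAAAGCTTTTAATATCAGTCGA	MDC018873.313	22	-	10447	No star found	0	0	5	6	10
miRC30	TCCCTCAAGGGCTTCCAATATT	MDC004268.215	22	+	9006	No star found	0	0	0	10	10
miRC31	TCCATAATTTTTCCAGATCAA	MDC005072.383	21	+	9885	No star found	0	0	8	0	8
miRC32	TGGTTTGGTTGGAAAACGGCT	MDC006935.286	21	-	27531	No star found	0	7	0	0	7
miRC33	AATTAGGCTGGCATTAGACAA	MDC009589.310	21	+	3312	No star found	6	0	0	0	6
miRC34	TGGTGATAGGATAGTTGGAAG	MDC010150.221	21	-	29453	No star found	6	0	0	0	6
miRC35	TACTGTTATAATGGCATTCCC	MDC001086.52	21	+	12332	No star found	5	0	0	0	5
miRC36	CTCAATTTGAACGCGTGGCTA	MDC015454.116	21	+	3773	No star found	0	5	0	0	5
miRC37	TGGCCTTGGTGGAAGAGATCC	MDC000614.265	21	-	5670	No star found	0	4	0	0	4
miRC38	TGGGCCTGGTCAGGAGGATCC	MDC018501.179	21	-	2535	No star found	0	4	0	0	4
miRC39	TTAAATACAAGCAGGAGCTCT	MDC011810.169	21	+	42284	No star found	0	3	0	0	3
miRC40	CACCTGGGACTTGCAGCCATG	MDC009540.166	21	+	1015	No star found	3	0	0	0	3
miRC41	CATCCGAATTACCAATAACTG	MDC009746.72	21	+	18725	No star found	0	0	3	0	3
miRC42	ATAGATGGAAGCTACCAACCC	MDC013676.252	21	+	6707	No star found	0	0	0	3	3
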