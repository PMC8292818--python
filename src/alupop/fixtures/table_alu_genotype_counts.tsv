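locus	genotype	Hani	Jinuo	Lisu	Nu	Jingpo	Bulang	Wa	Dai	Maonan	Zhuang	Tu	Yugur	Han-Yunnan
AluDPB2	11	38	29	24	29	50	44	35	37	34	30	28	23	57
AluDPB2	12	75	35	38	38	37	39	52	58	32	56	51	52	87
AluDPB2	22	36	11	17	15	8	26	22	26	12	15	31	18	42
AluDQA2	11	148	74	77	81	76	104	108	113	78	96	84	81	185
AluDQA2	12	1	0	1	1	18	5	1	6	0	5	24	7	1
AluDQA2	22	0	1	1	0	1	0	0	2	0	0	2	5	0
AluDQA1	11	14	3	13	15	3	0	5	4	1	13	21	5	28
AluDQA1	12	9	4	3	2	0	1	13	4	2	1	7	8	60
AluDQA1	22	126	68	63	65	92	108	91	113	75	87	82	80	98
AluDRB1	11	95	46	51	49	52	59	50	45	37	27	89	68	124
AluDRB1	12	45	25	25	28	39	43	49	63	36	56	20	23	57
AluDRB1	22	9	4	3	5	4	7	10	13	5	18	1	2	5
AluORF10	11	128	61	59	67	65	76	80	46	34	39	82	75	128
AluORF10	12	17	13	20	13	27	29	28	61	32	50	25	14	51
AluORF10	22	4	1	0	2	3	4	1	14	12	12	3	4	7
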