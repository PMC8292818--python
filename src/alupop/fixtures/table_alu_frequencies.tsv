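locus	allele	Hani	Jinuo	Lisu	Nu	Jingpo	Bulang	Wa	Dai	Maonan	Zhuang	Tu	Yugur	Han-Yunnan	Japanese	Caucasians
AluDPB2	1	0.507	0.620	0.544	0.585	0.721	0.583	0.560	0.545	0.641	0.574	0.486	0.527	0.540	0.500	0.546
AluDPB2	2	0.493	0.380	0.456	0.415	0.279	0.417	0.440	0.455	0.359	0.426	0.514	0.473	0.460	0.500	0.454
AluDQA2	1	0.997	0.987	0.981	0.994	0.895	0.977	0.995	0.959	1.000	0.975	0.873	0.909	0.997	0.990	0.790
AluDQA2	2	0.003	0.013	0.019	0.006	0.105	0.023	0.005	0.041	0.000	0.025	0.127	0.091	0.003	0.010	0.210
AluDQA1	1	0.124	0.067	0.184	0.195	0.032	0.005	0.106	0.050	0.026	0.134	0.223	0.097	0.312	0.432	0.503
AluDQA1	2	0.876	0.933	0.816	0.805	0.968	0.995	0.894	0.950	0.974	0.866	0.777	0.903	0.688	0.568	0.497
AluDRB1	1	0.789	0.780	0.804	0.768	0.753	0.739	0.683	0.632	0.705	0.545	0.900	0.855	0.820	0.775	0.744
AluDRB1	2	0.211	0.220	0.196	0.232	0.247	0.261	0.317	0.368	0.295	0.455	0.100	0.145	0.180	0.225	0.256
AluORF10	1	0.916	0.900	0.873	0.896	0.826	0.830	0.862	0.632	0.641	0.634	0.859	0.882	0.825	0.855	0.764
AluORF10	2	0.084	0.100	0.127	0.104	0.174	0.170	0.138	0.368	0.359	0.366	0.141	0.118	0.175	0.145	0.236
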