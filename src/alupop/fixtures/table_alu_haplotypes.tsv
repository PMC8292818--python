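label	AluDPB2	AluDQA2	AluDQA1	AluDRB1	AluORF10	Hani	Jinuo	Lisu	Nu	Jingpo	Bulang	Wa	Dai	Maonan	Zhuang	Tu	Yugur	Han-Yunnan	Japanese	Caucasians
H1	1	1	1	1	1	0.016	0.040	0.059	0.063	0.005	0.005	0.022	0.009	0.007	0.043	0.075	0.038	0.102	0.176	0.140
H2	1	1	1	1	2			0.006	0.010	0.011		0.009	0.015		0.056	0.012	0.005	0.031		
H3	1	1	1	2	1	0.007		0.006	0.006							0.016	0.006	0.014	0.021	0.040
H4	1	1	1	2	2														0.006	
H5	1	1	2	1	1	0.332	0.386	0.335	0.283	0.433	0.311	0.343	0.229	0.293	0.144	0.221	0.305	0.264	0.126	0.153
H6	1	1	2	1	2			0.010	0.050	0.037	0.063	0.020	0.062	0.155	0.031	0.040	0.052	0.039	0.051	0.023
H7	1	1	2	2	1	0.073	0.107	0.071	0.167	0.081	0.156	0.117	0.083	0.090	0.141	0.043	0.072	0.047	0.106	0.021
H8	1	1	2	2	2	0.075	0.074	0.043		0.092	0.025	0.049	0.125	0.096	0.140	0.010	0.004	0.040		0.033
H9	1	2	1	1	1			0.006					0.011			0.016	0.018		0.010	0.080
H10	1	2	1	1	2								0.000							0.004
H11	1	2	1	2	1	0.003											0.002			
H12	1	2	1	2	2															0.005
H13	1	2	2	1	1			0.006	0.006	0.052			0.006		0.010	0.050	0.020	0.003		0.013
H14	1	2	2	1	2										0.004	0.003				0.034
H15	1	2	2	2	1		0.013						0.004			0.001				
H16	1	2	2	2	2					0.010	0.023				0.006		0.005			
H17	2	1	1	1	1	0.094	0.021	0.099	0.108	0.011		0.070		0.010	0.021	0.087	0.028	0.159	0.091	0.091
H18	2	1	1	1	2		0.006		0.008	0.005			0.015	0.009	0.008	0.008			0.061	0.015
H19	2	1	1	2	1	0.004												0.005	0.052	0.053
H20	2	1	1	2	2															0.004
H21	2	1	2	1	1	0.347	0.319	0.238	0.205	0.156	0.352	0.206	0.204	0.195	0.206	0.297	0.320	0.179	0.198	0.095
H22	2	1	2	1	2		0.008	0.036	0.035		0.008	0.014	0.061	0.036	0.017	0.051	0.034	0.042	0.028	0.036
H23	2	1	2	2	1	0.040	0.014	0.045	0.058	0.045	0.007	0.104	0.066	0.046	0.064	0.013	0.027	0.051	0.036	0.011
H24	2	1	2	2	2	0.009	0.012	0.030		0.019	0.051	0.042	0.089	0.063	0.104		0.018	0.023		0.075
H25	2	2	1	1	1											0.009			0.010	0.060
H26	2	2	1	2	1															0.005
H27	2	2	1	2	2							0.005								0.007
H28	2	2	2	1	1			0.006		0.043			0.020		0.005	0.032	0.035			
H29	2	2	2	2	1												0.011			0.003
H30	2	2	2	2	2											0.017				
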