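allele	Hani	Jinuo	Lisu	Nu	Jingpo	Bulang	Wa	Dai	Maonan	Zhuang	Tu	Yugur	Han-Yunnan	Japanese	Caucasians
DRB1*01:01	0.013		0.013	0.006	0.026						0.064	0.048	0.024	0.08	0.095
DRB1*01:02			0.006												0.014
DRB1*01:03															0.011
DRB1*03:01	0.007						0.018	0.058	0.045	0.129	0.023	0.065	0.035		0.126
DRB1*03:05													0.003		
DRB1*04:01			0.006			0.005					0.027	0.043	0.003	0.02	0.109
DRB1*04:02												0.005	0.003		0.006
DRB1*04:03	0.017	0.04		0.018	0.005	0.018	0.014	0.012	0.006		0.005	0.038	0.016	0.035	0.006
DRB1*04:04									0.013		0.005	0.016	0.003		0.043
DRB1*04:05			0.038	0.024	0.026	0.023	0.028	0.054	0.09	0.015	0.068	0.054	0.059	0.135	
DRB1*04:06			0.006	0.03	0.011	0.005	0.014	0.021	0.006	0.015	0.014	0.022	0.027	0.025	
DRB1*04:07			0.006											0.01	0.02
DRB1*04:08												0.011		0.01	0.003
DRB1*04:10			0.019	0.006			0.009				0.009		0.008	0.01	
DRB1*07:01	0.003	0.013	0.006	0.012	0.021	0.005	0.055	0.008			0.073	0.065	0.062		0.144
DRB1*08:01	0.003											0.016			0.014
DRB1*08:02			0.006	0.012							0.005	0.022	0.008	0.035	
DRB1*08:03	0.03	0.087	0.076	0.11	0.047	0.014	0.037	0.004	0.071	0.015	0.059	0.027	0.089	0.07	
DRB1*08:04												0.011			0.003
DRB1*08:09								0.004				0.005			
DRB1*08:10															0.003
DRB1*08:27													0.003		
DRB1*09:01	0.027	0.007	0.051	0.024	0.042	0.014	0.005	0.112	0.103	0.05	0.127	0.134	0.159	0.2	0.023
DRB1*09:09													0.003		
DRB1*10:01	0.003				0.016			0.008		0.02	0.045	0.054	0.003	0.005	0.006
DRB1*11:01	0.013	0.047	0.044	0.031	0.021		0.005	0.021	0.026	0.05	0.105	0.048	0.054	0.01	0.06
DRB1*11:03															0.017
DRB1*11:04											0.005	0.005	0.008		0.006
DRB1*11:06			0.006	0.037	0.016	0.05	0.018	0.004							
DRB1*11:31													0.003		
DRB1*11:52													0.003		
DRB1*12:01	0.003		0.006	0.018							0.077	0.054	0.011	0.02	0.026
DRB1*12:02	0.322	0.407	0.209	0.238	0.453	0.55	0.326	0.099	0.16	0.045	0.086	0.054	0.164	0.025	
DRB1*12:19													0.003		
DRB1*13:01			0.019	0.012			0.073			0.005	0.014	0.043	0.011		0.063
DRB1*13:02			0.013	0.006	0.011	0.005		0.025		0.015	0.018		0.038	0.03	0.049
DRB1*13:03		0.007		0.012		0.005		0.037	0.064	0.025					0.006
DRB1*13:28													0.003		
DRB1*14:01	0.208	0.153	0.108	0.14	0.026	0.032	0.014	0.112	0.122	0.139	0.045	0.043	0.027	0.04	0.017
DRB1*14:02											0.009		0.003		
DRB1*14:03				0.018							0.014	0.005	0.008	0.03	
DRB1*14:04	0.118		0.12	0.012	0.021	0.005	0.069	0.033	0.006	0.005			0.005		
DRB1*14:05	0.02	0.027						0.012	0.013	0.005	0.027	0.016	0.008	0.015	
DRB1*14:06														0.01	
DRB1*14:07			0.019										0.003		
DRB1*14:10	0.017		0.013												
DRB1*14:18										0.015					
DRB1*14:25						0.014									
DRB1*14:32													0.005		
DRB1*14:35													0.003		
DRB1*15:01	0.044	0.04	0.057	0.037	0.058	0.073	0.092	0.087	0.096	0.168	0.018	0.065	0.073	0.05	0.103
DRB1*15:02	0.07	0.167	0.108	0.085	0.1	0.124	0.087	0.136	0.058	0.139	0.041	0.022	0.035	0.125	0.011
DRB1*15:04	0.067	0.007	0.038	0.098	0.063	0.037	0.133						0.008		
DRB1*15:11					0.011										
DRB1*15:15				0.006	0.005										
DRB1*16:01			0.006								0.009				0.014
DRB1*16:02	0.013			0.006	0.021	0.023	0.005	0.153	0.122	0.149	0.009	0.011	0.022	0.01	
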