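lineage	Average-10	Hani	Dai	Han-Yunnan	Japanese	Caucasians
DRB1*01	64	68		100	75	100
DRB1*03	25		59	3		
DRB1*04	8		20	9	2	5
DRB1*07	11	50				
DRB1*08	10		50	6	5	
DRB1*09			13	3		
DRB1*10			100			50
DRB1*11			17			
DRB1*12	2		29	4		
DRB1*13	20		41	5		
DRB1*14	4	13	53	9		
DRB1*15	95	54	49	86	83	100
DRB1*16	94	50	26	87	100	100
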