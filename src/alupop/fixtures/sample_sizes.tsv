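population	n
Hani	149
Jinuo	75
Lisu	79
Nu	82
Jingpo	95
Bulang	109
Wa	109
Dai	121
Maonan	78
Zhuang	101
Tu	110
Yugur	93
Han-Yunnan	186
Japanese	100
Caucasians	174
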