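# subtype -> parent class map for polymorph labels (editable)
subtype	parent
AD-PHF	AD
AD-SF	AD
CBD_T1	CBD
CBD_T2	CBD
CTE_T1	CTE
CTE_T2	CTE
AGD_T1	AGD
AGD_T2	AGD
GGT_T1	GGT
GGT_T2	GGT
GGT_T3	GGT
GPT_T1	GPT
GPT_T2	GPT
PSP	PSP
PiD	PiD
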