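layer	element	free_percent	predominant_species	predominant_percent
upper	Al	12	AlSO4+	83
upper	As(V)		H2AsO4-	89
upper	Co	74	Co2+	74
upper	Cu	66	Cu2+	66
upper	Fe(III)	5.0	FeSO4+	51.0
upper	Mn	76.2	Mn2+	76.2
upper	Ni	68.6	Ni2+	68.6
upper	Zn	63.9	Zn2+	63.9
chemocline	Al	13	AlSO4+	78
chemocline	As(V)		H2AsO4-	9
chemocline	Co	73	Co2+	73
chemocline	Cu	47	CuSO4	53
chemocline	Fe(II)	69.1	Fe2+	69.1
chemocline	Mn	76.0	Mn2+	76.0
chemocline	Ni	37.5	NiSO4	62.2
chemocline	Zn	52.7	Zn2+	52.7
deep	Al	6	AlSO4+	72
deep	As(III)		H3AsO3	100
deep	Co	80	Co2+	80
deep	Cu	45	CuSO4	55
deep	Fe(II)	76.4	Fe2+	76.4
deep	Mn	81.8	Mn2+	81.8
deep	Ni	44.3	NiSO4	54.9
deep	Zn	14.0	Zn(SO4)2-2	67.0
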