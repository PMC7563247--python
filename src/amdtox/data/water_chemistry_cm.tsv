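layer	element	conc_ug_per_L
upper	SO4	2500000
upper	Cl	15000
upper	Al	140000
upper	As(V)	100
upper	Co	2010
upper	Cu	6010
upper	Fe(III)	118000
upper	Mn	19000
upper	Ni	443
upper	Zn	13000
upper	PO4-P	50
upper	NH4-N	25
chemocline	SO4	3900000
chemocline	Cl	14000
chemocline	Al	158000
chemocline	As(V)	502
chemocline	Co	1310
chemocline	Cu	60
chemocline	Fe(II)	951000
chemocline	Mn	35200
chemocline	Ni	655
chemocline	Zn	35200
chemocline	PO4-P	50
chemocline	NH4-N	400
deep	SO4	12100000
deep	Cl	22000
deep	Al	5090
deep	As(III)	17200
deep	As(V)	0.13
deep	Co	2040
deep	Cu	50
deep	Fe(II)	6310000
deep	Mn	116000
deep	Ni	917
deep	Zn	109000
deep	PO4-P	3000
deep	NH4-N	536
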