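layer	element	tpf1_printed	tpf2_printed
upper	Al	1600	190
upper	As(V)	0.7
upper	Co	106	78
upper	Cu	670	440
upper	Fe(III)	120	6.0
upper	Mn	110	90
upper	Ni	9.0	6.0
upper	Zn	110	70
chemocline	Al	1800	230
chemocline	As(V)	3.3
chemocline	Co	69	50
chemocline	Cu	6.7	3.1
chemocline	Fe(II)	950	660
chemocline	Mn	210	160
chemocline	Ni	13	5.0
chemocline	Zn	290	150
deep	Al	60	4.0
deep	As(III)	110
deep	Co	107	85
deep	Cu	5.6	2.5
deep	Fe(II)	6300	4800
deep	Mn	700	570
deep	Ni	18	8.0
deep	Zn	910	130
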