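element	cccf_ug_per_L
Al	87
As(III)	150
As(V)	150
Co	19
Cu	9.0
Fe(III)	1000
Fe(II)	1000
Ni	52
Zn	120
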