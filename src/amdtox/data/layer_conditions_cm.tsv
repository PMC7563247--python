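layer	depth_m	pH	orp_mV	sc_mS_cm	temperature_C
upper	3	2.6	575	3.4	17.0
chemocline	11	3.95	60	4.85	12.5
deep	35	4.5	41	12.1	18.3
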