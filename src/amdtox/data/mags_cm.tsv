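mag_id	taxonomy	rel_abundance	completeness	contamination
A_CRE_07	d__Archaea;p__Crenarchaeota;c__Nitrososphaeria;o__Nitrososphaerales;f__UBA183;g__UBA183	0.7	95	5
A_EUR_01	d__Archaea;p__Thermoplasmatota;c__Thermoplasmata;o__Thermoplasmatales;f__GCA-001856825;g__GCA-001856825	10.3	94	3
A_EUR_06	d__Archaea;p__Thermoplasmatota;c__Thermoplasmata;o__Thermoplasmatales;f__Thermoplasmataceae	1.2	94	1
A_MIC_10	d__Archaea;p__Micrarchaeota;c__Micrarchaeia;o__Micrarchaeales;f__Micrarchaeaceae;g__UBA12276	0.5	77	0
A_NAN_12	d__Archaea;p__Nanoarchaeota;c__Nanoarchaeia;o__Woesearchaeales;f__UBA525;g__UBA153	0.4	77	0
B_ACI_09	d__Bacteria;p__Acidobacteriota;c__Acidobacteriae	0.5	81	4
B_ACT_02	d__Bacteria;p__Actinobacteriota;c__Thermoleophilia;o__BMS3ABIN01;f__BMS3ABIN01	2.8	87	1
B_ACT_11	d__Bacteria;p__Actinobacteriota;c__Thermoleophilia;o__BMS3ABIN01;f__BMS3ABIN01	0.4	90	3
B_CHL_03	d__Bacteria;p__Chloroflexota;c__Dehalococcoidia;o__SZUA-161;f__SZUA-161	2.3	98	2
B_DOR_08	d__Bacteria;p__Dormibacterota;c__Dormibacteria;o__UBA8260;f__UBA8260	0.7	88	0
B_NIT_04	d__Bacteria;p__Nitrospirota;c__Thermodesulfovibrionia;o__Thermodesulfovibrionales;f__JdFR-88	2.3	100	1
B_PAT_13	d__Bacteria;p__Patescibacteria;c__Paceibacteria;o__UBA6257;f__Colwellbacteraceae	0.2	75	0
B_PRO_05	d__Bacteria;p__Desulfobacterota;c__Desulfomonilia;o__Desulfomonilales;f__Desulfomonilaceae	1.3	92	1
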