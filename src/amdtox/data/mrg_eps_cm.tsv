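ko	gene_symbols	primary_metal	metals	mechanism	specific	source	pathway	description
K16567	exoQ			Extracellular Sequestration	False	EPS	Wzx-Wzy dependent pathway	Exopolysaccharide production protein ExoQ (polymerase wzy)
K16695	wzxC			Extracellular Sequestration	False	EPS	Wzx-Wzy dependent pathway	Lipopolysaccharide exporter (flippase wzx)
K03328	wzx			Extracellular Sequestration	False	EPS	Wzx-Wzy dependent pathway	Polysaccharide transporter, PST family (flippase wzx; rfbX, gumJ)
K16692	wzc			Extracellular Sequestration	False	EPS	Wzx-Wzy dependent pathway	Tyrosine-protein kinase Etk/Wzc (polysaccharide co-polymerase PCP)
K00903	epsB			Extracellular Sequestration	False	EPS	Wzx-Wzy dependent pathway	Protein-tyrosine kinase (polysaccharide co-polymerase PCP)
K16554	exoP			Extracellular Sequestration	False	EPS	Wzx-Wzy dependent pathway	Polysaccharide biosynthesis transport protein (polysaccharide co-polymerase PCP)
K13661	gumC			Extracellular Sequestration	False	EPS	Wzx-Wzy dependent pathway	GumC protein (polysaccharide co-polymerase PCP)
K01991	wza			Extracellular Sequestration	False	EPS	Wzx-Wzy dependent pathway	Polysaccharide biosynthesis/export protein (outer membrane transporter OPX)
K09689	kpsT			Extracellular Sequestration	False	EPS	ABC-transport	Capsular polysaccharide transport system ATP-binding protein
K09688	kpsM			Extracellular Sequestration	False	EPS	ABC-transport	Capsular polysaccharide transport system permease protein
K10107	kpsE			Extracellular Sequestration	False	EPS	ABC-transport	Capsular polysaccharide transport system permease protein (PCP)
K16557	exoA			Extracellular Sequestration	False	EPS	Glycosyltransferase	Succinoglycan biosynthesis protein ExoA
K16556	exoM			Extracellular Sequestration	False	EPS	Glycosyltransferase	Succinoglycan biosynthesis protein ExoM
K16703	wcaL			Extracellular Sequestration	False	EPS	Glycosyltransferase	Colanic acid/amylovoran biosynthesis glycosyltransferase
K13657	gumH			Extracellular Sequestration	False	EPS	Glycosyltransferase	Alpha-1,3-mannosyltransferase
K00694	bcsA			Extracellular Sequestration	False	EPS	Glycosyltransferase	Cellulose synthase (UDP-forming)
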