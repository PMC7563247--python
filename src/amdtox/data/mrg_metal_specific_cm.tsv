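ko	gene_symbols	primary_metal	metals	mechanism	specific	source	pathway	description
K03327	TC.MATE	Al	Al	Export	False	KEGG		Multidrug and toxic compound extrusion (MATE) family transporter, Al and multidrug tolerance; also known as SLC47A, norM, mdtK, dinF
K17686	copA	Cu	Cu	Export	True	BacMet		P-type Cu+ transporter; also involved in resistance to sodium acetate and Ag in certain organisms
K01533	copB	Cu	Cu	Export	True	BacMet		P-type Cu+ transporter; copB also known as copA_3, copF_3, cadA
K19591	cueR	Cu	Cu	Regulation	True	BacMet		MerR family transcriptional regulator, Cu efflux regulator (ybbI)
K22552	mmcO	Cu	Cu	Biochemical Transformation	True	KEGG		Multicopper oxidase, oxidizes Cu with oxygen as acceptor; also known as copA_1, copA_2, cueO
K07665	copR	Cu	Cu	Regulation	True	KEGG		Two-component system OmpR family, copper resistance phosphate regulon response regulator CusR
K07787	cusA	Cu	Cu,Ag	Export	False	KEGG		Cu(I)/Ag(I) efflux system membrane protein (silA)
K07798	cusB	Cu	Cu,Ag	Export	False	KEGG		Cu(I)/Ag(I) efflux system membrane protein (silB)
K07810	cusF	Cu	Cu,Ag	Export	False	KEGG		Cu(I)/Ag(I) efflux system periplasmic binding protein (silF)
K07213	copZ	Cu	Cu	Export	True	BacMet		Copper chaperone
K07243	ftr1	Fe	Fe,Pb	Import	False	BacMet		High affinity low-pH Fe(II) transporter; also involved in Pb resistance
K13283	fieF	Fe	Fe,Zn,Co,Cd,Ni	Export	False	BacMet		Ferrous-iron efflux pump; also involved in efflux of Zn/Co/Cd/Ni
K02012	fbpA	Fe	Fe,Ga	Import	False	BacMet		Iron(III) transport system substrate-binding protein (afuA); also involved in Ga resistance
K02011	fbpB	Fe	Fe,Ga	Import	False	BacMet		Iron(III) transport system permease protein (afuB); also involved in Ga resistance
K18683	rus	Fe	Fe,Cu	Biochemical Transformation	False	literature		Rusticyanin, involved in Fe(II) oxidation, potentially in copper resistance
K03711	fur	Fe	Fe	Regulation	True	KEGG		Fur family transcriptional regulator, ferric uptake regulator (zur, furB)
K00522	fth1	Fe	Fe	Intracellular Accumulation	True	KEGG		Ferritin heavy chain, iron storage, mainly eukaryotic
K02217	ftnA	Fe	Fe,Cu,Mn	Intracellular Accumulation	False	BacMet		Ferritin, iron storage; also involved in resistance to Cu and Mn
K03594	bfr	Fe	Fe	Intracellular Accumulation	True	KEGG		Bacterioferritin, iron storage
K23242	mntP	Mn	Mn	Export	True	BacMet		Manganese efflux protein
K03322	mntH	Mn	Mn,Zn,Fe	Import	False	BacMet		Manganese transport protein involved in Mn, Zn, and Fe uptake
K11924	mntR	Mn	Mn,Fe,Zn,Cd,Co	Regulation	False	KEGG		DtxR family transcriptional regulator, manganese transport regulator; responds to Mn(II), Fe(II), Zn(II), Cd(II), Co(II)
K01534	zntA	Zn	Zn,Cd,Co,Pb	Export	False	KEGG		Zn2+/Cd2+-exporting ATPase; also involved in Co and Pb extrusion
K09815	znuA	Zn	Zn	Import	True	KEGG		Zinc transport system substrate-binding protein
K09816	znuB	Zn	Zn	Import	True	KEGG		Zinc transport system permease protein
K09817	znuC	Zn	Zn	Import	True	KEGG		Zinc transport system ATP-binding protein
K15726	czcA	Zn	Zn,Co,Cd,Ni	Export	False	BacMet		Cobalt-zinc-cadmium efflux system protein; also involved in Ni and Co resistance
K15727	czcB	Zn	Zn,Co,Cd,Ni	Export	False	BacMet		Cobalt-zinc-cadmium efflux system membrane fusion protein
K15725	czcC	Zn	Zn,Co,Cd,Ni	Export	False	BacMet		Cobalt-zinc-cadmium efflux system outer membrane protein
K16264	czcD	Zn	Zn,Co,Cd,Ni	Export	False	BacMet		Cobalt-zinc-cadmium efflux system protein CzcD
K21903	cadC	Zn	Zn,Cd,Bi,Pb	Regulation	False	BacMet		ArsR family transcriptional regulator, Cd-responsive repressor; involved in Cd/Bi/Zn/Pb resistance
K03709	troR	Zn	Zn,Mn,Fe	Regulation	False	BacMet		Mn-dependent transcriptional regulator; involved in resistance to Zn/Mn/Fe and hydrogen peroxide
K15584	nikA	Ni	Ni	Import	True	KEGG		Nickel transport system substrate-binding protein
K15586	nikC	Ni	Ni	Import	True	KEGG		Nickel transport system permease protein
K07785	ncrA	Ni	Ni,Co,Cd,Zn,Fe	Export	False	BacMet		Ni/Co transporter; also involved in Co/Cd/Zn/Fe resistance (nrsD, rcnA, yohM)
K08970	ncrC	Ni	Ni,Co,Cd,Zn,Fe	Export	False	BacMet		Ni/Co transporter accessory protein
K03325	acr3	As	As	Export	True	KEGG		Arsenite transporter
K01551	arsA	As	As	Export	True	KEGG		Arsenite/tail-anchored protein-transporting ATPase
K03893	arsB	As	As	Export	True	KEGG		Arsenite pump membrane protein
K03741	arsC	As	As	Biochemical Transformation	True	KEGG		Arsenate reductase (thioredoxin as acceptor)
K22547	arsC_HAC1	As	As	Biochemical Transformation	True	KEGG		Arsenate reductase (glutathione or glutaredoxin as acceptor)
K08355	aioB	As	As	Biochemical Transformation	True	KEGG		Arsenite oxidase small subunit (aoxA)
K02038	pstA	As	As	Biochemical Transformation	False	BacMet		Phosphate transport system permease, As(V) uptake
K02036	pstB	As	As	Biochemical Transformation	False	BacMet		Phosphate transport system ATP-binding protein, As(V) uptake
K02037	pstC	As	As	Biochemical Transformation	False	BacMet		Phosphate transport system permease, As(V) uptake
K02040	pstS	As	As	Biochemical Transformation	False	BacMet		Phosphate transport system substrate-binding protein, As(V) uptake
K03892	arsR	As	As	Regulation	True	KEGG		Transcriptional repressor, As resistance regulation
K09043	acr1	As	As	Regulation	True	KEGG		AP-1-like transcription factor, As resistance regulation
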