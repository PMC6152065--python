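name	ax	bx	by	dx	dy
Brimstone	N	6	8*	2	12
Cappelle-Desprez	N	7	-	2	12
Cheyenne	2*	7	9	5	10
Chinese Spring	N	7	8	2	12
Clement	N	6	8*	2	12
Gabo	2*	17	18	2	12
Glenlea	2*	7OE	8*	5	10
Insignia	1	20x	20y	5	10
Nanbu-komugi	1	7	8	4	12
Neepwa	2*	7	9	5	10
Norin61	2*	7	8	2.2	12
Orca	N	7	-	2	12
Sukang	2*	13	16	2	12
Petrel	N	7	-	5	10
Soissons	2*	7	8	5	10
Thesee	N	6	8*	2	12
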