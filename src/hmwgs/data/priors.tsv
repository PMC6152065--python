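name	ax	bx	by	dx	dy
Alchan	2*	7	8	5	10
Anbaek	N	7	9	2	12
Baekjoong	2*	13	16	2.2	12
Chungkye	N	7	8	2.2	12
Dabun	2*	7	8	2.2	12
Dahong	N	7	8	2.2	12
Dajoong	2*	13	16	2.2	12
Eunpa	N	7	9	2.2	12
Geuru	N	7	8	2.2	12
Gobun	N	7	9	2	12
Goso	2*	7	8	2.2	12
Hanbaek	2*	7	8	5	10
Jeokjoong	2*	13	16	2.2	12
Jinpoom	N	7	8	2.2	12
Joeun	N	13	16	2.2	12
Jokyung	1	7	8	5	10
Jonong	N	7	8	2	12
Jopoom	N	13	16	2.2	12
Keumkang	2*	7	8	5	10
Milsung	N	7	8	2.2	12
Namhae	N	7	8	2.2	12
Ol	N	7	8	2.2	12
Olgeuru	2*	7	8	2.2	12
Saeol	N	7	8	2.2	12
Seodun	N	7	8	2.2	12
Sinmichal	2*	7	8	2.2	12
Sinmichal1	N	7	9	2.2	12
Suan	2*	7	8	2.2	12
Sukang	2*	13	16	2	12
Tapdong	2*	7	8	5	10
Uri	N	7	8	2.2	12
Younbaek	2*	13	16	2.2	12
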