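name	ax	bx	by	dx	dy	is_new
Alchan	2*	7	8	5	10	0
Anbaek	N	7	9	2	12	0
Baekchal	2*	7	8*	5	10	1
Baekjoong	2*	13	16	2.2	12	0
Chungkye	N	7	8	2.2	12	0
Dabun	2*	7	8	2.2	12	0
Dahong	N	7	8	2.2	12	0
Dajoong	2*	13	16	2.2	12	0
Eunpa	N	7	9	2.2	12	0
Geuru	N	7	8	2.2	12	0
Gobun	N	7	9	2	12	0
Goso	2*	7	8	2.2	12	0
Hanbaek	2*	7	8	5	10	0
Hojoong	2*	7	8	2.2	12	1
Jeokjoong	2*	13	16	2.2	12	0
Jinpoom	N	7	8	2.2	12	0
Joa	2*	7	8	2.2	12	1
Joeun	N	13	16	2.2	12	0
Jojoong	N	13	16	2.2	12	1
Jokyung	1	7	8	5	10	0
Jonong	N	7	9	2	12	0
Joongmo2008	N	17	18	5	10	1
Joongmo2012	2*	7	8	5	10	1
Jopoom	N	13	16	2.2	12	0
Keumkang	2*	7	8	5	10	0
Milsung	N	7	8	2.2	12	0
Namhae	N	7	8	2.2	12	0
Ol	N	7	8	2.2	12	0
Olgeuru	2*	7	8	2.2	12	0
Saeol	N	7	8	2.2	12	0
Seodun	N	7	8	2.2	12	0
Sinmichal	2*	7	8*	2.2	12	0
Sinmichal1	N	7	9	2	12	0
Suan	2*	7	8	2.2	12	0
Sukang	2*	13	16	2	12	0
Tapdong	2*	7	8	5	10	0
Uri	N	7	8	2.2	12	0
Younbaek	2*	13	16	2.2	12	0
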