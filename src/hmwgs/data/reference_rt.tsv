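type	label	mean_rt	sd_rt	n_cultivars	n_analyses	rsd_pct
Ax	1	40.307	0.078	2	9	0.195
Ax	2*	40.354	0.077	7	18	0.190
Bx	6	38.516	0.059	3	8	0.154
Bx	7	38.842	0.077	9	25	0.199
Bx	7OE	38.770	0.078	1	6	0.201
Bx	13	37.285	0.030	1	3	0.081
Bx	17	39.075	0.053	1	5	0.138
Bx	20x	39.603	0.061	1	4	0.155
By	8	36.060	0.083	4	12	0.231
By	8*	33.948	0.098	4	10	0.290
By	9	34.091	0.085	2	5	0.252
By	16	35.604	0.039	1	3	0.109
By	18	34.022	0.108	1	5	0.319
By	20y	33.894	0.043	1	3	0.127
Dx	2	35.195	0.114	8	24	0.325
Dx	2.2	34.428	0.082	1	3	0.238
Dx	4	35.269	0.094	1	3	0.267
Dx	5	34.792	0.119	6	17	0.343
Dy	10	26.736	0.101	6	10	0.377
Dy	12	26.528	0.098	10	18	0.370
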