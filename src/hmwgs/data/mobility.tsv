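type	label	rank
Dx	2.2	1
Ax	1	2
Dx	2	3
Dx	4	4
Dx	5	5
Ax	2*	6
Bx	6	7
Bx	7	8
Bx	7OE	8
Bx	13	9
Bx	17	10
Bx	20x	11
By	8	12
By	8*	13
By	9	14
By	16	15
By	18	16
By	20y	17
Dy	10	18
Dy	12	18
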