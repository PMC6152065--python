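bx	by
6	8*
7	8
7	8*
7	9
7OE	8*
13	16
17	18
20x	20y
7	-
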