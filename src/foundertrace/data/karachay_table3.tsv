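sample_id	population	variant1	variant2	D17S831	D17S1798	D17S829	D17S1828	D17S1876
BM	Karachay-Cherkessia	c.1015G>A	c.1015G>A	1|1	1|1	3|3	3|3	9|9
SF	Karachay-Cherkessia	c.1015G>A	c.1015G>A	1|8	1|3	3|3	3|3	9|10
TSR	Karachay-Cherkessia	c.1015G>A	c.1015G>A	1|1	1|1	3|3	3|3	9|9
KI	Karachay-Cherkessia	c.1015G>A	c.18_21del	3|3	1|7	3|7	3|3	9|8
BRA	Kabardino-Balkaria	c.1015G>A	c.681G>A	3|7	1|2	3|7	3|4	7|6
ESA	Karachay-Cherkessia	c.1015G>A	c.1015G>A	1|1	2|2	3|3	3|3	9|9
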