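marker	allele	count	total
D17S831	1	3	38
D17S1876	9	2	38
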