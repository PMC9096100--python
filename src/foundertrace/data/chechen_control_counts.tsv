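marker	allele	count	total
D17S831	6	3	34
D17S1828	5	10	34
D17S1876	7	3	34
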