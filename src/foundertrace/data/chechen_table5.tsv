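sample_id	population	variant1	variant2	D17S831	D17S1798	D17S829	D17S1828	D17S1876
MM	Chechnya	c.518A>G	c.518A>G	4|4	1|1	1|1	5|5	7|7
MSU	Chechnya	c.518A>G	c.518A>G	6|6	1|2	1|1	5|2	7|1
IAM	Chechnya	c.518A>G	c.518A>G	9|1	2|1	1|1	8|5	7|7
EIS	Ingushetia	c.518A>G	c.518A>G	3|3	2|3	1|1	8|5	7|7
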