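variant	consequence_class	novel
57 kb del	LoF	0
c.518A>G	missense	0
c.1015G>A	missense	0
c.433C>T	LoF	0
c.785G>A	LoF	1
c.18_21del	LoF	0
ex.6-13del	LoF	1
ex.4-5del	LoF	0
c.699_700del	LoF	0
c.451A>G	missense	0
c.283G>T	LoF	0
ex.6-7del	LoF	1
c.140+2dup	splice_VUS	1
c.627C>A	missense	1
c.681G>A	synonymous_splice	0
c.681+1G>A	LoF	0
c.323del	LoF	0
c.613G>A	missense	0
c.198_218del	LoF	1
c.1000del	LoF	1
c.505G>T	missense	1
c.413G>A	LoF	1
c.450G>A	LoF	1
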