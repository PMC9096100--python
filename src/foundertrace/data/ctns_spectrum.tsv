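variant	chromosomes
57 kb del	20
c.518A>G	11
c.1015G>A	10
c.433C>T	6
c.785G>A	5
c.18_21del	3
ex.6-13del	2
ex.4-5del	2
c.699_700del	2
c.451A>G	2
c.283G>T	2
ex.6-7del	2
c.140+2dup	2
c.627C>A	2
c.681G>A	1
c.681+1G>A	1
c.323del	1
c.613G>A	1
c.198_218del	1
c.1000del	1
c.505G>T	1
c.413G>A	1
c.450G>A	1
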