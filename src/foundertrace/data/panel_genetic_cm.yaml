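unit: genetic_cM
locus_position: 10.02
markers:
  - {name: D17S831, position: 6.60}
  - {name: D17S1798, position: 6.60}
  - {name: D17S829, position: 10.02, intragenic: true}
  - {name: D17S1828, position: 10.02}
  - {name: D17S1876, position: 10.72}
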