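unit: physical
locus_position: 3.553
markers:
  - {name: D17S831, position: 1.910}
  - {name: D17S1798, position: 2.706}
  - {name: D17S829, position: 3.550, intragenic: true}
  - {name: D17S1828, position: 3.810}
  - {name: D17S1876, position: 4.345}
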