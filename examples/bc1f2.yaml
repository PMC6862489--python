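# BC1F2 of the d60-combining scheme: Koshihikari crossed to the
# GW2-d60 double-donor segregant, the F1 selfed to 112 plants.
name: bc1f2
loci:
  - {name: GW2, alleles: [GW2, gw2], chromosome: "2", position_mb: 8.1}
  - {name: D60, alleles: [d60, D60], chromosome: "2", position_mb: 13.5}
  - {name: Gal, alleles: [Gal, gal]}
map:
  groups:
    - {loci: [GW2, D60], r: [0.176]}
    - {loci: [Gal], r: []}
lethality:
  combinations: [[d60, gal]]
  sexes: both
founders:
  Koshihikari:
    haplotypes:
      - [gw2, D60, gal]
      - [gw2, D60, gal]
  GW2-d60-segregant:
    haplotypes:
      - [GW2, d60, Gal]
      - [GW2, d60, Gal]
steps:
  - {name: BC1F1, cross: [Koshihikari, GW2-d60-segregant], n: 1}
  - {name: BC1F2, self: BC1F1, n: 112}
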