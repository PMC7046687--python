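# Simulate the full study-shaped cohort (115 samples, ~20k sites over
# 3 x 1 Mb chromosomes) with default caller noise, then run the whole
# pipeline on the emitted VCFs.
seed: 7
simulate: {}
filter: {}
diagnostic:
  eu_strains: [EUR_WILD]
phylo:
  reps: 100
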