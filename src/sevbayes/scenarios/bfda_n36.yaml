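# Fixed-n BFDA: n = 36 per group, true effect d = 0.4, thresholds 3 and 1/3.
name: bfda_n36
kind: bfda
parameters:
  n_per_group: 36
  effect_size_d: 0.4
  n_sims: 10000
  seed: 20220815
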