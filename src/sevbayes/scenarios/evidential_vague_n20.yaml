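# Expected |log BF| of the H_v-vs-encompassing design with N=20 per arm.
name: evidential_vague_n20
kind: evidential-value
parameters:
  label: H_v
  region_a: [0.0, 0.5]
  region_b: [0.5, 1.0]
  n_a: 20
  n_b: 20
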