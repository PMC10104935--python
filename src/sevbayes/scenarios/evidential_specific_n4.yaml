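# Expected |log BF| of the H_s-vs-encompassing design with N=4 per arm.
name: evidential_specific_n4
kind: evidential-value
parameters:
  label: H_s
  region_a: [0.2, 0.3]
  region_b: [0.7, 0.8]
  n_a: 4
  n_b: 4
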