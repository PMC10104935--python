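# PTSD treatment comparison: interval hypothesis H_v vs the encompassing model.
name: ptsd_vague_n20
kind: bf
parameters:
  label: H_v
  region_a: [0.0, 0.5]
  region_b: [0.5, 1.0]
  n_a: 20
  n_b: 20
  s_a: 5
  s_b: 15
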