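# Cooling-system accident: does xbar = 152 severely support mu >= 153?
name: water_plant
kind: sev
parameters:
  mu0: 150.0
  sigma: 10.0
  n: 100
  alpha: 0.025
  xbar: 152.0
  mu1: 153.0
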