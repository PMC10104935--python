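# Same observed mean and claim, but the default state of affairs is 100:
# the severity value is identical, exposing the mu0-invariance of SEV.
name: water_plant_mu0_100
kind: sev
parameters:
  mu0: 100.0
  sigma: 10.0
  n: 100
  alpha: 0.025
  xbar: 152.0
  mu1: 153.0
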