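# Moderate sample: moderate inventory and surface concentrations.
params:
  F_T: 0.276
  F_R: 0.011
  F_B: 0.528
  F_A: 0.092
  k_P: 615.508
  psi_MP: 0.193
  R_F_MP: 0.993
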