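# Low surface concentration sample: efficient marine-snow uptake,
# small seafloor return.
params:
  F_T: 0.137
  F_R: 0.003
  F_B: 0.132
  F_A: 0.003
  k_P: 0.424
  psi_MP: 0.260
  R_F_MP: 1.029
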