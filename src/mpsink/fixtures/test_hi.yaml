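# High particle load sample: high input and seafloor return.
params:
  F_T: 0.329
  F_R: 0.074
  F_B: 0.888
  F_A: 0.098
  k_P: 833.290
  psi_MP: 0.132
  R_F_MP: 1.489
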