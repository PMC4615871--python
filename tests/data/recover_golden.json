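{
  "true_a": 0.01,
  "true_R": 70.0,
  "true_C": 20000,
  "eps_w": 5e-05,
  "seed": 123,
  "n_clones_observed": 811,
  "S": 13475,
  "a_star": 0.0197524671,
  "R_star": 67.34272359,
  "UC_estimate": 10130.170401,
  "a_rel_err": 0.97524671,
  "R_rel_err": -0.03796109
}
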