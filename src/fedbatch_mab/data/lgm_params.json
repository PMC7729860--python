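{
  "mu_max": 0.058,
  "K_glc": 0.75,
  "K_gln": 0.075,
  "KI_lac": 172.0,
  "KI_amm": 28.5,
  "mu_d_max": 0.03,
  "K_d_amm": 1.76,
  "K_lysis": 0.0551,
  "Y_x_glc": 1.06e8,
  "m_glc": 4.85e-14,
  "Y_x_gln": 5.57e8,
  "m_gln": -6.7e-13,
  "K_d_gln": 0.0096,
  "Y_lac_glc": 1.4,
  "Y_amm_gln": 0.427,
  "gamma": 0.1,
  "lambda_mab": 7.21e-9
}
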