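{
  "name": "SPBR",
  "description": "Nominal batch set-point: all substrates and cells loaded at t = 0, zero feed.",
  "t_f": 100.0,
  "arcs": [
    {"F_L": 0.0, "GLC_in": 29.1, "GLN_in": 4.9, "Xv_in": 2e8}
  ],
  "initial": {"mAb_0": 80.6, "AMM_0": 0.31, "LAC_0": 0.0, "V_L0": 1.0},
  "search_space": null,
  "provenance": {
    "note": "Batch reference run; the single zero-feed arc carries the initial loads (29.1 mM GLC, 4.9 mM GLN, 2e8 cells/L) through the inlet-coupled initial condition.",
    "reported_max_mab_mg_per_L": 1254.6
  },
  "known_inconsistencies": []
}
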