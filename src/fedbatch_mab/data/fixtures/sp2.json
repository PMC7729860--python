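{
  "name": "SP2",
  "description": "Fed-batch optimum found under wide search ranges, five 20 h arcs.",
  "t_f": 100.0,
  "arcs": [
    {"F_L": 1e-3, "GLC_in": 141.63, "GLN_in": 17.76, "Xv_in": 4.38e9},
    {"F_L": 1e-3, "GLC_in": 55.81,  "GLN_in": 9.52,  "Xv_in": 4.20e9},
    {"F_L": 1e-3, "GLC_in": 25.60,  "GLN_in": 16.58, "Xv_in": 3.98e9},
    {"F_L": 1e-3, "GLC_in": 126.92, "GLN_in": 21.77, "Xv_in": 3.21e9},
    {"F_L": 1e-3, "GLC_in": 94.62,  "GLN_in": 14.43, "Xv_in": 1.20e9}
  ],
  "initial": {"mAb_0": 80.6, "AMM_0": 0.31, "LAC_0": 0.0, "V_L0": 1.0},
  "search_space": {
    "F_L": [1e-4, 5e-2],
    "GLC_in": [25.0, 150.0],
    "GLN_in": [5.0, 25.0],
    "Xv_in": [2e8, 5e9],
    "max_dilution_fraction": 0.25
  },
  "provenance": {
    "note": "Reference optimum under the wide search ranges (best reported titer).",
    "reported_max_mab_mg_per_L": 6098.4,
    "reported_final_volume_L": 1.1
  },
  "known_inconsistencies": [
    "The reported consumption row (44.46 mmol GLC, 8.00 mmol GLN, 1.7e9 cells fed) is about 5x the closed-form sum over these arcs (8.89 mmol GLC, 1.60 mmol GLN, 3.39e8 cells); the per-arc policy above is treated as ground truth and SP2 consumption figures are not used as references.",
    "The reported specific-productivity biomass basis (1.7e9 cells) matches neither the fed-cells sum nor the initial load."
  ]
}
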