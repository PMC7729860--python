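{
  "name": "SP3",
  "description": "Fed-batch optimum found under wide search ranges, two 50 h arcs.",
  "t_f": 100.0,
  "arcs": [
    {"F_L": 1e-3, "GLC_in": 88.65,  "GLN_in": 21.58, "Xv_in": 3.21e9},
    {"F_L": 1e-3, "GLC_in": 137.97, "GLN_in": 20.65, "Xv_in": 1.2e9}
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
    "note": "Reference optimum with only two arcs under the wide search ranges.",
    "reported_max_mab_mg_per_L": 5700.1,
    "reported_final_volume_L": 1.1,
    "reported_consumed_GLC_mmol": 11.33,
    "reported_consumed_GLN_mmol": 2.11,
    "reported_biomass_fed_cells": 2.2e8
  },
  "known_inconsistencies": []
}
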