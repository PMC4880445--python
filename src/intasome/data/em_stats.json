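{
  "comment": "Single-particle bookkeeping for the excisive Holliday-junction complex reconstruction; used as numeric inputs by the retained-particle arithmetic.",
  "micrographs": 1359,
  "particles_picked": 66033,
  "particles_final_reconstruction": 10956,
  "retained_percent_printed": 17,
  "pixel_size_final_A": 2.8,
  "sharpening_bfactor_A2": -2500.0,
  "map_resolution_A": 11.0,
  "phase_randomization_limit_A": 18.0,
  "mask_margin_A": 15.0,
  "fsc_threshold_halfmaps": 0.143,
  "fsc_threshold_model": 0.5
}
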