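{
 "table_id": "strain_TX1",
 "notes": "Band positions from the isolated sulfur-oxidizing chemoautotroph Guyparkeria sp. TX1 after 5 days of 13C-bicarbonate labeling. The 13C positions are observed values; incomplete isotopic labeling is established for the phenylalanine band (1003 -> 985 cm-1) and may also affect the Cyt c positions, so these should not be read as fully-labeled endmembers.",
 "bands": [
  {"name": "pyrrole_breathing", "mode_label": "pyrrole breathing", "c12": 749.0, "c13": 728.0, "window_halfwidth": 10.0, "required": true, "role": "cyt_c"},
  {"name": "nu_CN", "mode_label": "ν(C-N)", "c12": 1125.0, "c13": 1115.0, "window_halfwidth": 10.0, "required": true, "role": "cyt_c"},
  {"name": "delta_CH", "mode_label": "δ(C-H)", "c12": 1312.0, "c13": 1306.0, "window_halfwidth": 10.0, "required": true, "role": "cyt_c"},
  {"name": "nu_CC", "mode_label": "ν(C-C)", "c12": 1584.0, "c13": 1534.0, "window_halfwidth": 10.0, "required": true, "role": "cyt_c"},
  {"name": "phe_ring", "mode_label": "ring breathing", "c12": 1003.0, "c13": 985.0, "window_halfwidth": 10.0, "required": true, "role": "phenylalanine", "caveat": "observed_partial"}
 ]
}
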