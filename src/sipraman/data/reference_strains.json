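{
 "table_id": "reference_strains",
 "notes": "Cytochrome c and phenylalanine band positions measured on pure chemoautotrophic reference strains (Thiobacimonas profunda, Halothiobacillus diazotrophicus, Thiomicrorhabdus indica) under 12C- vs 13C-bicarbonate. Alternative Cyt c positions 749/1129/1312/1589 cm-1 appear in summary text; the values here anchor all reported shifts and are used as defaults.",
 "bands": [
  {"name": "pyrrole_breathing", "mode_label": "pyrrole breathing", "c12": 747.0, "c13": 725.0, "window_halfwidth": 10.0, "required": true, "role": "cyt_c"},
  {"name": "nu_CN", "mode_label": "ν(C-N)", "c12": 1125.0, "c13": 1115.0, "window_halfwidth": 10.0, "required": true, "role": "cyt_c"},
  {"name": "delta_CH", "mode_label": "δ(C-H)", "c12": 1312.0, "c13": 1300.0, "window_halfwidth": 10.0, "required": true, "role": "cyt_c"},
  {"name": "nu_CC", "mode_label": "ν(C-C)", "c12": 1584.0, "c13": 1536.0, "window_halfwidth": 10.0, "required": true, "role": "cyt_c"},
  {"name": "phe_ring", "mode_label": "ring breathing", "c12": 1002.0, "c13": 965.0, "window_halfwidth": 10.0, "required": true, "role": "phenylalanine"}
 ]
}
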