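{
 "table_id": "sediment_enrichment",
 "notes": "Band positions from gradient-density-isolated cells of enriched coastal sediment incubated with 2 mM 12C- or 13C-bicarbonate; Cyt c positions differ slightly from pure reference strains.",
 "bands": [
  {"name": "pyrrole_breathing", "mode_label": "pyrrole breathing", "c12": 747.0, "c13": 725.0, "window_halfwidth": 10.0, "required": true, "role": "cyt_c"},
  {"name": "nu_CN", "mode_label": "ν(C-N)", "c12": 1125.0, "c13": 1115.0, "window_halfwidth": 10.0, "required": true, "role": "cyt_c"},
  {"name": "delta_CH", "mode_label": "δ(C-H)", "c12": 1310.0, "c13": 1300.0, "window_halfwidth": 10.0, "required": true, "role": "cyt_c"},
  {"name": "nu_CC", "mode_label": "ν(C-C)", "c12": 1584.0, "c13": 1531.0, "window_halfwidth": 10.0, "required": true, "role": "cyt_c"},
  {"name": "phe_ring", "mode_label": "ring breathing", "c12": 1000.0, "c13": 965.0, "window_halfwidth": 10.0, "required": true, "role": "phenylalanine"}
 ]
}
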