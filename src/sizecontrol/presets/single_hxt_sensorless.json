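{
  "genotype": "single_HXT_sensorless",
  "glucose_pct": 0.1,
  "dox_ng_ml": 1000,
  "Km_mM": 10.0,
  "description": "Single TET-driven transporter in the sensorless (snf3 rgt2) background."
}
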