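{
  "genotype": "single_HXT",
  "glucose_pct": 0.1,
  "dox_ng_ml": 1000,
  "Km_mM": 10.0,
  "description": "Transporterless background expressing one mid-affinity transporter (HXT2-like, Km ~10 mM) from a TET promoter; influx titrated by doxycycline."
}
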