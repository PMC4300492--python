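{
  "genotype": "transporterless_sensorless",
  "glucose_pct": 0.1,
  "description": "Transporterless plus snf3 rgt2 deletion: no influx and no external-glucose sensing."
}
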