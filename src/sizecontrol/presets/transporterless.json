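{
  "genotype": "transporterless",
  "glucose_pct": 0.1,
  "description": "All hexose transporters deleted; sensors intact. No glucose influx at any external level."
}
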