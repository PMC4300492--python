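{
  "genotype": "WT",
  "glucose_pct": 2.0,
  "description": "Wild type: full transporter complement, Snf3/Rgt2 sensors intact."
}
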