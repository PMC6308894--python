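{
 "Sauron-S878": {
  "end": 66,
  "start": 40,
  "strand": "plus"
 },
 "jgHCO2198": {
  "end": 353,
  "start": 327,
  "strand": "minus"
 }
}
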