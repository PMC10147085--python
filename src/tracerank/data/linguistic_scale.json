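{
  "VH": [0.75, 1.0, 1.0],
  "H": [0.5, 0.75, 1.0],
  "M": [0.25, 0.5, 0.75],
  "L": [0.0, 0.25, 0.5],
  "VL": [0.0, 0.0, 0.25]
}
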