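{
  "description": "Gender composition of the cohort.",
  "states": ["Women", "Men"],
  "counts": [185, 1233],
  "frequencies": [0.1305, 0.8695],
  "total": 1418
}
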