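{
  "description": "Sample distribution of the family-history-of-hearing-problems flag.",
  "states": ["No", "Yes"],
  "counts": [1239, 179],
  "frequencies": [0.8738, 0.1262],
  "total": 1418
}
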