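{
  "description": "Sample distribution of the binaural-loss index groups (counts per group).",
  "groups": ["1", "2", "3", "4", "5"],
  "intervals_pct": [[0.0, 0.0], [0.0, 15.0], [15.0, 30.0], [30.0, 45.0], [45.0, 100.0]],
  "counts": [1221, 163, 28, 4, 2],
  "total": 1418
}
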