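{
  "description": "Sample distribution by age quintile, with the integer-year bounds of each group.",
  "groups": ["<29", "29-34", "35-39", "40-48", ">=49"],
  "counts": [273, 276, 269, 303, 297],
  "frequencies": [0.19, 0.20, 0.19, 0.21, 0.21],
  "age_bounds": [[17, 28], [29, 34], [35, 39], [40, 48], [49, 66]],
  "total": 1418
}
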