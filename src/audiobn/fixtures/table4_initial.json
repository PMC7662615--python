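{
  "description": "Initial (single-predictor) conditional distributions of the binaural-loss group, in percent.",
  "loss_groups": ["1", "2", "3", "4", "5"],
  "baseline": [89.04, 9.89, 1.01, 0.06, 0.00],
  "gender": {
    "Women": [96.08, 3.74, 0.18, 0.00, 0.00],
    "Men": [87.95, 10.84, 1.14, 0.07, 0.00]
  },
  "age_group": {
    "<29": [95.97, 3.86, 0.00, 0.17, 0.00],
    "29-34": [95.25, 4.52, 0.23, 0.00, 0.00],
    "35-39": [93.75, 6.22, 0.03, 0.00, 0.00],
    "40-48": [85.93, 12.93, 1.12, 0.02, 0.00],
    ">=49": [74.83, 21.38, 3.67, 0.12, 0.00]
  },
  "family_history": {
    "No": [89.26, 9.65, 1.03, 0.06, 0.00],
    "Yes": [87.25, 11.87, 0.84, 0.04, 0.00]
  }
}
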