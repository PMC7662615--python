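{
  "description": "Loss-group distribution conditional on gender and family history, in percent.",
  "loss_groups": ["1", "2", "3", "4", "5"],
  "baseline": [89.04, 9.89, 1.01, 0.06, 0.00],
  "rows": {
    "Women": {
      "No": [96.17, 3.65, 0.18, 0.00, 0.00],
      "Yes": [94.86, 4.98, 0.12, 0.00, 0.03]
    },
    "Men": {
      "No": [88.14, 10.62, 1.17, 0.07, 0.00],
      "Yes": [86.52, 12.53, 0.91, 0.04, 0.00]
    }
  }
}
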