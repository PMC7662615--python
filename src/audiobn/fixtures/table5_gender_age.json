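{
  "description": "Loss-group distribution conditional on gender and age group, in percent.",
  "loss_groups": ["1", "2", "3", "4", "5"],
  "baseline": [89.04, 9.89, 1.01, 0.06, 0.00],
  "rows": {
    "Women": {
      "<29": [98.01, 1.99, 0.00, 0.00, 0.00],
      "29-34": [97.46, 2.15, 0.38, 0.00, 0.01],
      "35-39": [97.84, 2.16, 0.00, 0.00, 0.00],
      "40-48": [93.15, 6.56, 0.29, 0.00, 0.00],
      ">=49": [90.47, 9.27, 0.25, 0.01, 0.00]
    },
    "Men": {
      "<29": [95.69, 4.11, 0.00, 0.19, 0.00],
      "29-34": [94.80, 5.01, 0.20, 0.00, 0.00],
      "35-39": [92.68, 7.29, 0.04, 0.00, 0.00],
      "40-48": [85.13, 13.64, 1.21, 0.02, 0.00],
      ">=49": [73.42, 22.47, 3.98, 0.13, 0.00]
    }
  }
}
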