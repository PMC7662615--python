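{
  "description": "Loss-group distribution conditional on family history, gender and age group, in percent. Keyed family_history -> gender -> age_group.",
  "loss_groups": ["1", "2", "3", "4", "5"],
  "baseline": [89.04, 9.89, 1.01, 0.06, 0.00],
  "rows": {
    "No": {
      "Women": {
        "<29": [98.04, 1.96, 0.00, 0.00, 0.00],
        "29-34": [97.48, 2.13, 0.39, 0.00, 0.00],
        "35-39": [97.92, 2.08, 0.00, 0.00, 0.00],
        "40-48": [93.22, 6.47, 0.31, 0.00, 0.00],
        ">=49": [90.56, 9.18, 0.25, 0.01, 0.00]
      },
      "Men": {
        "<29": [95.76, 4.03, 0.00, 0.21, 0.00],
        "29-34": [94.93, 4.86, 0.21, 0.00, 0.00],
        "35-39": [92.70, 7.27, 0.04, 0.00, 0.00],
        "40-48": [85.10, 13.67, 1.21, 0.02, 0.00],
        ">=49": [73.58, 22.09, 4.21, 0.13, 0.00]
      }
    },
    "Yes": {
      "Women": {
        "<29": [97.35, 2.65, 0.00, 0.00, 0.00],
        "29-34": [97.14, 2.39, 0.31, 0.00, 0.16],
        "35-39": [96.78, 3.22, 0.00, 0.00, 0.00],
        "40-48": [92.48, 7.43, 0.09, 0.00, 0.00],
        ">=49": [89.49, 10.23, 0.25, 0.03, 0.00]
      },
      "Men": {
        "<29": [95.03, 4.97, 0.00, 0.00, 0.00],
        "29-34": [93.62, 6.26, 0.12, 0.00, 0.00],
        "35-39": [92.52, 7.42, 0.05, 0.00, 0.00],
        "40-48": [85.31, 13.46, 1.21, 0.02, 0.00],
        ">=49": [72.29, 25.15, 2.41, 0.14, 0.00]
      }
    }
  }
}
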