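{
  "description": "Loss-group distribution conditional on age group and family history, in percent.",
  "loss_groups": ["1", "2", "3", "4", "5"],
  "baseline": [89.04, 9.89, 1.01, 0.06, 0.00],
  "rows": {
    "<29": {"No": [96.04, 3.78, 0.00, 0.19, 0.00], "Yes": [95.19, 4.81, 0.00, 0.00, 0.00]},
    "29-34": {"No": [95.38, 4.38, 0.24, 0.00, 0.00], "Yes": [93.99, 5.85, 0.14, 0.00, 0.02]},
    "35-39": {"No": [93.82, 6.15, 0.03, 0.00, 0.00], "Yes": [93.15, 6.81, 0.04, 0.00, 0.00]},
    "40-48": {"No": [85.95, 12.92, 1.11, 0.02, 0.00], "Yes": [85.82, 13.03, 1.13, 0.02, 0.00]},
    ">=49": {"No": [75.04, 20.98, 3.87, 0.12, 0.00], "Yes": [73.31, 24.27, 2.28, 0.14, 0.00]}
  }
}
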