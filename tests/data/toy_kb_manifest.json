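{
  "n_findings": 4,
  "n_explanations": 3,
  "findings_per_explanation": {
    "1": 1,
    "2": 1,
    "3": 1
  },
  "top_findings": [
    [
      "F001",
      3
    ],
    [
      "F002",
      2
    ],
    [
      "F004",
      1
    ]
  ],
  "pct_le5": 100.0,
  "pct_ge10": 0.0,
  "pct_single_numerator": 1
}
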