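{
  "labels": ["EOA", "DCD", "CTRL"],
  "class_sizes": [18, 13, 29],
  "row_percentages": [
    [61.4, 21.9, 16.6],
    [3.8, 82.5, 13.7],
    [4.3, 1.2, 94.5]
  ],
  "row_percentage_sd": [
    [6.3, 6.2, 4.9],
    [4.7, 5.9, 3.8],
    [1.5, 1.9, 2.2]
  ],
  "note": "Mean confusion-matrix row percentages over 100 repeated leave-one-participant-out runs; rows are actual classes, columns predicted."
}
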