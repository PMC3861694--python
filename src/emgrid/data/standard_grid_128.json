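{
  "name": "standard_128",
  "n_rows": 12,
  "n_cols": 12,
  "pitch_mm": 10.0,
  "missing_blocks": [
    [[1, 2], [1, 4]],
    [[11, 12], [1, 4]]
  ],
  "reference_col": 3
}
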