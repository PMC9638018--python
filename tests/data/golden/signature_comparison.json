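{
  "groups": [
    "SDHB_D",
    "other"
  ],
  "mean_scores": [
    3.4720810028905076,
    5.206536958730114
  ],
  "n": [
    18,
    27
  ],
  "p_value": 1.3998319318365758e-07,
  "statistic": 15.5,
  "statistic_name": "U",
  "test": "wilcoxon"
}
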