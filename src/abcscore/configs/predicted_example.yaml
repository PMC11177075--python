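# Example predicted CPC 1-2 probabilities per ABC score for calibration plots.
# These are illustrative derivation-style rates; supply your own derivation
# cohort's per-score rates for a real calibration assessment.
0: 0.002
1: 0.006
2: 0.030
3: 0.100
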