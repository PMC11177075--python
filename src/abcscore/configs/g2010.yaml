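# Synthetic cohort calibrated to the 2010 guideline group (arrests 2012-2014):
# exact proportions of the reconstructed stratum table (N = 186,228;
# CPC 1-2 = 1,420).
n_records: 160000
score_distribution: [0.5671059132, 0.3454206671, 0.0750424211, 0.0124309986]
outcome_probabilities:
  0: [0.0014581814, 0.007]
  1: [0.0070732352, 0.020]
  2: [0.0359212880, 0.050]
  3: [0.1334773218, 0.110]
years: [2012, 2013, 2014]
component_style:
  age_young_mean: 60.0
  age_young_sd: 10.0
  age_old_mean: 81.0
  age_old_sd: 8.0
  witnessed_given_not_b: 0.20
  pad_given_c: 0.146   # PAD is 1,764 of 12,113 C=1 patients in this group
seed: 0
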