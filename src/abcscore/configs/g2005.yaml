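# Synthetic cohort calibrated to the 2005 guideline group (arrests 2007-2009)
# of the nationwide validation cohort: score marginal and per-score CPC 1-2
# probabilities are the exact proportions of the reconstructed stratum table
# (N = 162,710; CPC 1-2 = 1,161).
n_records: 160000
score_distribution: [0.5376067851, 0.3601683978, 0.0856001475, 0.0166246696]
outcome_probabilities:
  0: [0.0017948190, 0.008]
  1: [0.0057676228, 0.020]
  2: [0.0292935095, 0.050]
  3: [0.0953789279, 0.100]
years: [2007, 2008, 2009]
component_style:
  age_young_mean: 60.0
  age_young_sd: 10.0
  age_old_mean: 81.0
  age_old_sd: 8.0
  witnessed_given_not_b: 0.21
  pad_given_c: 0.069   # PAD is 848 of 12,290 C=1 patients in this group
seed: 0
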