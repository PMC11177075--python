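# Synthetic cohort calibrated to the 2015 guideline group (arrests 2017-2019):
# exact proportions of the reconstructed stratum table (N = 190,794;
# CPC 1-2 = 1,801).
n_records: 160000
score_distribution: [0.5747036070, 0.3415516211, 0.0713544451, 0.0123903268]
outcome_probabilities:
  0: [0.0017054264, 0.006]
  1: [0.0089770739, 0.020]
  2: [0.0464962539, 0.050]
  3: [0.1675126904, 0.110]
years: [2017, 2018, 2019]
component_style:
  age_young_mean: 60.0
  age_young_sd: 10.0
  age_old_mean: 81.0
  age_old_sd: 8.0
  witnessed_given_not_b: 0.20
  pad_given_c: 0.182   # PAD is 2,083 of 11,475 C=1 patients in this group
seed: 0
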