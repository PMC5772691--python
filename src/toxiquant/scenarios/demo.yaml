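# Default synthetic demo scenario for `toxiquant run`.
# Response noise and matrix parameters are mid-range plausible values;
# the case profile defaults (fileio.default_profile) anchor the blood decay
# 9.8 -> 1.5 ng/mL between days 6 and 11 with 1.8 d / 81 d half-lives.
seed: 1
out_dir: toxiquant-out
weighting: "1/x"
ion_ratio_tolerance: 0.30
precision_limit: 20.0
bias_limit: 20.0
noise_cv: 0.03
matrix_effect: 0.90
recovery: 0.70
lot_cv: 0.05
between_day_cv: 0.05
n_levels: 7
qc_replicates: 6
qc_days: 6
n_lots: 5
aliquot_rsd: 0.25
n_aliquots: 6
windows:
  - [6.0, 11.0]
  - [64.0, 422.0]
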