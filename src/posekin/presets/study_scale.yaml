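# Production-scale parameterization for GPCR-ligand binding-pose MSM studies:
# 4 slow TICA components, 100 microstates, 96 ns lag, 500 posterior samples,
# 0.7 metastable-membership filter. Metastable-state counts are per condition
# (chosen after implied-timescale and Chapman-Kolmogorov inspection).
tica_lag: 50
n_tica: 4
n_microstates: 100
msm_lag: null
msm_lag_ns: 96.0
n_ms:
  D2R_WT: 2
  D3R_WT: 2
  D2R_E2.65A: 3
  D3R_E2.65A: 3
n_bayes_samples: 500
membership_threshold: 0.7
seed: 0
out_dir: null
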