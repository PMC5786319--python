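# Desk-scale configuration matched to the default synthetic 3-state scenario
# (stationary [0.50, 0.30, 0.20], 40 trajectories x 5000 frames, dt 0.3 ns).
tica_lag: 5
n_tica: 4
n_microstates: 100
msm_lag: 2
msm_lag_ns: null
n_ms: 3
n_bayes_samples: 500
membership_threshold: 0.7
seed: 0
out_dir: null
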