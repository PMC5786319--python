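"""MSM-guided adaptive seeding of additional sampling rounds.

Round 0 mimics an unlucky campaign start: trajectories launched from the
dominant basin plus one very short probe in a rare, kinetically distant
basin. The seeding rule picks single-frame and under-sampled between-state
microstates as restart points; each round extends the data from those frames
until the equilibrium probabilities stop changing by 5 percentage points.
"""
from posekin import adaptive, synthetic

spec, trajs, simulator = synthetic.rare_intermediate_campaign(seed=102)
cfg = adaptive.CampaignConfig(tica_lag=2, n_tica=3, n_microstates=50, msm_lag=2,
                              n_ms=3, max_rounds=5, steps_per_seed=1500, seed=102)

errors = []


def watch(rnd, dtrajs, model, part):
    p_far = synthetic.estimated_basin_probability(part, dtrajs, simulator.hidden,
                                                  basin=2)
    errors.append(abs(p_far - spec.stationary[2]))


report = adaptive.run_iteration_loop(trajs, cfg, simulator, on_round=watch)

print(f"designed probability of the rare basin: {spec.stationary[2]:.2f}")
for rec, err in zip(report.rounds, errors):
    reasons = ", ".join(f"{k}: {v}" for k, v in rec.seed_reasons.items()) or "none"
    print(f"round {rec.round_index}: {rec.n_trajectories} trajectories, "
          f"{rec.n_seeds} seeds ({reasons}), |error in rare-basin pi| = {err:.3f}")
print(f"converged: {report.converged}")
print("\nThe error of the rare basin's equilibrium probability shrinks as the")
print("sampler restarts trajectories from its under-sampled microstates.")
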