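# posekin

Markov state model (MSM) analysis of dynamic ligand binding poses from
molecular-dynamics trajectories.

Ligands that engage a receptor through two linked pharmacophores — such as
the negative allosteric modulator SB269652 at the dopamine D2 and D3
receptors — often keep one moiety anchored in the orthosteric site while the
other exchanges between several poses in an accessory pocket. Kinetic
analysis of many short MD trajectories can resolve that exchange: which
metastable binding modes exist, what their equilibrium probabilities π are,
and how fast they interconvert. `posekin` packages the full analysis chain
for this problem, together with a synthetic-data generator that has exact
ground truth so every stage is testable without any trajectory download.

## What it computes

Given per-frame feature vectors (or coordinates plus a feature recipe —
ligand-nitrogen-to-Cβ distances within 7.0 Å, intramolecular distances and
ring-normal projections; 16 features in the canonical recipe):

1. **TICA** — the slow linear subspace from the generalized eigenproblem
   C(τ) v = λ C(0) v; projection on the leading components (4 by default),
   ranked by cumulative kinetic variance Σλ².
2. **Microstates** — k-means discretization (100 microstates by default),
   with a cross-validated variational score (sum of squared estimated
   eigenvalues on held-out trajectories) to compare microstate counts.
3. **Reversible MSM** — maximum-likelihood transition matrix P(τ) under
   detailed balance π_i P_ij = π_j P_ji; Bayesian uncertainty from 500
   posterior transition-matrix samples; implied timescales
   t_i = −τ/ln|λ_i|; validation by the Chapman–Kolmogorov test
   P(kτ) = P(τ)^k with bootstrapped 95% bands.
4. **Metastable states** — PCCA++ memberships χ; per-state equilibrium
   probabilities π_MS = χᵀπ with 1σ intervals; inter-state rates as inverse
   mean first passage times; frame filtering at >70% membership; state
   identity matching across conditions.
5. **Adaptive seeding** — restart-frame selection from single-frame and
   under-sampled between-state microstates, with a 5-percentage-point
   convergence rule on π_MS across sampling rounds.
6. **Conformational statistics** — posterior-weighted frame draws (3 × 500
   samples × 3 frames, or 3000 proportional to π_MS), contact-frequency
   tables (5.0 Å heavy-atom cutoff), H-bond frequencies, and distances
   between helical-subsegment centers of mass.
7. **Loop clustering** — iterative RMSF filtering (>5.0 Å excluded), Ward
   clustering of superposed pairwise RMSDs with a 5.0 Å / 5% cut rule, and
   population reweighting by π_MS.

## Worked example

```bash
python examples/01_simulate_and_estimate_msm.py
```

```
designed pi:   ['0.500', '0.300', '0.200']
recovered pi:  ['0.490', '0.282', '0.228']
largest |pi error|: 0.0277

MFPTs between metastable states (ns), estimated vs exact:
  0->1:   22.36 vs   22.50  (rel err 0.6%)
  0->2:   30.51 vs   31.87  (rel err 4.3%)
  1->0:   14.43 vs   15.00  (rel err 3.8%)
  1->2:   27.11 vs   28.12  (rel err 3.6%)
  2->0:   15.45 vs   15.00  (rel err 3.0%)
  2->1:   19.99 vs   18.75  (rel err 6.6%)
```

The generator simulated a 3-state pose-exchange system with designed
equilibrium probabilities [0.50, 0.30, 0.20]; the pipeline (TICA → k-means
→ reversible MSM → PCCA++) recovered each π within 0.03 and each mean
first passage time within 7% of the generating chain's exact linear-algebra
values on this reduced 12-trajectory run. The other scripts in `examples/` demonstrate model validation
(implied timescales and Chapman–Kolmogorov), an adaptive seeding campaign
that rescues an under-sampled rare basin, ensemble-weighted contact and
subsegment-distance statistics, and flexible-loop clustering.

For real trajectory data, load features with `posekin.io`, pick the
`study_scale` preset (`posekin.pipeline.load_preset`), and call
`posekin.pipeline.run_pipeline({condition: trajectories}, config)`.

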