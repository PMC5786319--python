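# Methods

## Scope and model

`posekin` estimates the metastable-state kinetics of a ligand's binding
poses from many (typically short) equilibrium MD trajectories. The
underlying model is a reversible discrete-time Markov chain on conformational
microstates: the analysis assumes the pooled trajectories sample an
equilibrium ensemble, that the dynamics projected on slow coordinates are
Markovian at the chosen lag time, and that detailed balance holds
(π_i P_ij = π_j P_ji). Everything reported downstream — equilibrium
probabilities of metastable states, inter-state rates, ensemble-weighted
structural statistics — derives from that chain.

## Featurization

The canonical binding-mode feature vector consists of (i) distances from
the ligand's nitrogen atoms to the Cβ atoms of candidate residues whose Cβ
lies within a cutoff of any nitrogen in one designated reference frame
(default 7.0 Å, boundary inclusive — the comparison is `≤`, which is
documented and tested because "within" is ambiguous at the boundary);
(ii) intramolecular distances fixing the orientation of the secondary
pharmacophore (defaults N4–N3 and N4–amide O); (iii) the signed projections
of the vectors from each aromatic-ring center of mass to a reference atom
(N4) onto the membrane normal. With 12 qualifying Cβ–N pairs this yields 16
features. For multi-condition runs the union of per-condition residue
selections is used so all conditions share one feature space, because TICA
and k-means are fitted on the combined data.

Ring and subsegment centers of mass are unweighted means over heavy atoms;
mass weighting is a flag, not the default. The hydrogen-bond criterion is
donor–acceptor heavy-atom distance ≤ 3.5 Å with donor–H···acceptor angle
≥ 120°, with a distance-only mode as an alternative; both are configuration
choices since no single geometric criterion is canonical. Contact tables
flag residues above 25% (listing) and 65% (display) frequency, strictly
greater in both cases.

Units are Å for coordinates and distances, ns for times; frames are
0-indexed.

## TICA

Covariances use the symmetrized pair estimator over all (t, t+τ) pairs
(frames near trajectory ends contribute only through the pairs they belong
to); C(τ) is symmetrized and C(0) regularized by ε·I with
ε = 1e-10 · trace/k, which makes near-duplicate distance features harmless
while changing well-conditioned problems below solver precision. The
generalized eigenproblem is solved densely; component signs are fixed by
making each component's largest-magnitude loading positive. The TICA lag is
a free parameter (default: the smallest MSM lag candidate); the number of
retained components defaults to 4, or can be chosen by a cumulative
kinetic-variance threshold. No Koopman reweighting is applied — the plain
symmetrized estimator matches the assumption of equilibrium data.

## Microstates and model selection

k-means (k-means++ initialization, one seeded run) discretizes the projected
space; 100 microstates is the shipped default. Cluster centers are stored so
frames from later sampling rounds are assigned to the *same* microstates —
this keeps metastable-state identities stable across adaptive rounds. Model
selection over k uses a cross-validated variational score: folds split whole
trajectories; for each candidate the training folds are re-discretized and a
reversible MSM estimated, and the score on held-out folds is the sum of
squared estimated eigenvalues of the leading m processes (m = 5 by default,
2 folds); the stationary process contributes 1, so k = 1 scores exactly 1.
Held-out states unseen in training drop their transition pairs.

## Reversible estimation

The maximum-likelihood reversible transition matrix is found by the
self-consistent fixed-point iteration on symmetric edge weights
x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j). Stopping: relative
log-likelihood change below 1e-12, with an additional edge-weight-change
floor of 1e-13 applied during the first 10,000 sweeps so that small,
well-conditioned problems are polished to full precision; beyond that the
likelihood criterion alone governs, because for nearly decomposable chains
the flat direction of the likelihood converges only at the rate of the
slowest physical process. If the 10⁶-sweep cap is reached the current
iterate is returned with a warning — every iterate derives from symmetric
weights, so detailed balance holds exactly regardless. Counting is
sliding-window and never crosses trajectory boundaries; analysis is
restricted to the largest connected component of the symmetrized count
graph, and the number of frames outside it is reported, never silently
dropped.

## Bayesian uncertainty

Posterior uncertainty over reversible transition matrices is sampled by a
Metropolis random walk on the logarithms of the symmetric edge weights (only
edges observed in either direction are sampled). One sweep updates every
edge once; per-edge step sizes scale as 2.4/√(1+counts) so acceptance stays
useful for both well- and poorly-sampled edges; burn-in is 10·n_states
sweeps and samples are one sweep apart by default; 500 samples is the
shipped default. The sampler targets the reversible likelihood with a flat
prior on the weights; the scale direction is neutral because all observables
(P, π, MFPTs, timescales) are scale-invariant. Empirically the posterior
mean matches the MLE and posterior SDs shrink as 1/√counts (both tested).
Summary intervals are central quantiles: 1σ = 68.27%, plus 95% where shown.

## Validation

Implied timescales t_i(τ) = −τ·dt/ln|λ_{i+1}(τ)| are computed per lag with
95% bands from the Bayesian ensemble; λ → 1 reports ∞ rather than
overflowing. The Chapman–Kolmogorov test initializes the population in each
metastable set, propagates it with P(τ)^k, and compares against a re-
estimate at lag kτ from the data, with 95% bands from bootstrapping whole
trajectories (500 bootstrap draws by default); a set passes when the
prediction stays inside the band at every k with sufficient data, and k
values beyond the data are reported as explicit gaps. The test demonstrably
detects a designed non-Markovian counterexample (a hidden three-state chain
observed through a two-state lumping whose two hidden states exit their
lump at very different rates).

## Metastable states, rates, matching

PCCA++ is implemented as the inner-simplex vertex construction on the
leading π-orthonormalized right eigenvectors; negative memberships (which
arise only for weakly metastable spectra) are clipped and rows renormalized
— on the near-decomposable chains this package targets, memberships are
crisp (≥ 0.99) and the full constrained-optimization refinement of PCCA+
would change nothing. Frames join a metastable state only when their
microstate's maximum membership exceeds 0.7; the rest form a first-class
"unassigned" pool consumed by the adaptive sampler. π_MS = χᵀπ. Rates are
inverse mean first passage times between crisp microstate sets, computed by
the absorbing-chain linear solve (source states weighted by π restricted to
the source); unreachable targets raise an error rather than returning
infinity. MS identities across conditions sharing one discretization are
matched greedily by shared crisp microstate count, ties broken by Jaccard
index then lower index; unmatched states get fresh labels.

## Adaptive seeding

Restart microstates are (i) single-frame microstates and (ii) microstates
with fewer than 10 frames whose top two metastable memberships differ by at
most 0.2 (the operationalization of "in between states"; the tolerance is
configurable). The representative restart frame is the microstate's frame
with the largest simulation time, ties broken by lowest trajectory id then
frame index — a reconstruction of "restart from late-stage frames",
documented as such. A campaign is converged when the largest absolute change
of any metastable state's equilibrium probability between rounds is below
0.05 (5 percentage points, read as absolute probability); the verdict is
symmetric in the two rounds, and running out of rounds yields an explicit
not-converged verdict. The propagation step is a simulator hook; the package
ships only the synthetic-chain simulator, but a real MD engine can implement
the same `run(selection, n_steps, seed)` interface.

## Ensemble-weighted structural statistics

Per replicate set (3) and per posterior sample (500), a few frames (3) are
drawn per metastable state with microstate probabilities proportional to
that sample's stationary law restricted to the state's eligible (filtered)
microstates; frames are uniform within the chosen microstate, a choice that
is unspecified territory and documented here. The alternative pooled draw
distributes a fixed total (3000) across metastable states proportionally to
π_MS with largest-remainder rounding. Histograms are weight-normalized per
state; statistics are invariant to frame order and weight duplication
(tested).

## Loop clustering

The stable residue set is found by iteratively excluding residues with RMSF
above 5.0 Å after superposition on the current set (two alignment
refinements against the running mean; residue RMSF is the mean of its
atoms' RMSF over backbone atoms N, CA, C, O — the atom set is a documented
choice). Known final selections can be supplied directly, bypassing the
filter. Pairwise RMSDs use per-pair optimal (Kabsch) superposition on the
selected backbone atoms, batched through SVD. Ward linkage is cut at the
smallest cluster count for which every cluster has mean intra-cluster
pairwise RMSD ≤ 5.0 Å or holds less than 5% of the frames; labels are
canonicalized by decreasing cluster size. Cluster populations are
reweighted by frame weights π_MS(state)/n_sampled(state) and normalized to
100%. Representative ensembles are the medoid plus its four nearest
neighbours.

## Synthetic data: what it emulates and what it does not

The generator produces (i) hidden metastable dynamics as a discrete-time
reversible chain with designed stationary law and exchange matrix (a
Metropolis construction guarantees detailed balance), so π and MFPTs have
exact linear-algebra ground truth; (ii) Gaussian diagonal-covariance feature
emissions around per-state means — the simplest emission model whose TICA
solution relates analytically to the chain's eigenvalues; (iii) toy
coordinate ensembles: a pseudo-loop whose per-state templates are scaled to
exact designed pairwise RMSDs, four pseudo-helical Cβ subsegments whose ring
"breathes" radially between states, and a pseudo-ligand with four nitrogens,
an amide oxygen and two rings. One global seed fans out to per-trajectory
substreams, so adding trajectories never reshuffles existing ones.

The default desk-scale scenario is 3 states with stationary
[0.50, 0.30, 0.20], Metropolis move probability 0.02 per step, 40
trajectories × 5000 frames at 0.3 ns/frame, 16 features with 4σ state
separation. Reduced sizes are used where a check needs many seeded repeats
(e.g. 8 × 1200 frames per Chapman–Kolmogorov repeat); these sizes are chosen
so sampling error stays well inside the tested tolerances.

The scenario's analysis lag is 2 frames (0.6 ns). MFPTs computed from a
τ-lagged chain are measured in multiples of τ·dt and therefore carry a
systematic upward bias of order τ·dt; at the designed exchange times
(15–32 ns) a lag of 2 frames keeps that bias below ~3%, while the
discretization is sharp enough (4σ state separation) that no longer lag is
needed for Markovianity.

What passing on synthetic data does *not* show: real MD features are
neither Gaussian nor conditionally independent given the metastable state,
real state boundaries are soft, trajectories may be non-equilibrium near
their starts, and force-field and sampling biases have no synthetic
counterpart. The tests validate the estimators and the pipeline logic, not
the physics of any particular receptor-ligand system.

## Numerical choices and degenerate inputs

Ties in k-means assignment go to the lowest center index; exact membership
ties at the 0.7 filter go to the unassigned pool; an all-zero RMSD matrix
yields a single cluster; eigenvalue 1 yields an infinite implied timescale,
reported as such. Validation thresholds: row sums and detailed balance at
1e-10, membership row sums at 1e-9, reweighted populations at 1e-6.
Matching of estimated to generating states in recovery checks uses the
majority hidden label of each state's filtered frames.

## Known limitations

No hidden-Markov or Koopman/VAMP estimators beyond the cross-validation
score; no fuzzy-committor coarse-grained rate theory (rates use crisp sets,
matching the inverse-MFPT definition); effective-counting corrections for
sliding-window counts are out of scope; the Bayesian sampler is a
random-walk MH scheme, adequate for the posterior widths tested here but
less efficient than specialized Gibbs samplers on very large sparse count
matrices; PDB/DCD input requires mdtraj and covers plain single-chain
topologies only.
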