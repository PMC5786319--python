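"""MSM-guided adaptive seeding of additional sampling rounds.

After each round of sampling the microstate model is inspected and two kinds
of microstates are selected as restart points for the next round:

* single-frame microstates — barely visited regions of the projected space;
* under-sampled microstates (< 10 frames by default) that are "in between"
  metastable states, operationalized as a gap of at most ``betweenness_tol``
  between their two largest metastable memberships.

The representative restart frame of a selected microstate is its frame with
the largest simulation time (ties: lowest trajectory id, then lowest frame
index) — restarting from late-stage frames favours relaxed configurations.
A sampling campaign is converged when the biggest change of any metastable
state's equilibrium probability between consecutive rounds is below 5
percentage points (absolute).

The actual propagation is delegated to a simulator hook so that real MD
engines can plug in; tests and examples use the synthetic generator, which
continues the hidden chain from the seed frame's hidden state.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coarse import coarse_grain
from .exceptions import ValidationError
from .msm import assign_to_centers, count_matrix, estimate_reversible_mle, kmeans_discretize
from .tica import fit_tica, project
from .types import DiscreteTrajectory, FeatureTrajectory

__all__ = [
    "SeedFrame", "SeedSelection", "select_seed_frames", "check_convergence",
    "ConvergenceVerdict", "CampaignConfig", "run_iteration_loop", "CampaignReport",
]


@dataclass(frozen=True)
class SeedFrame:
    microstate: int
    reason: str  # "single-frame" | "under-sampled-between-MS"
    trajectory_id: str
    trajectory_index: int
    frame_index: int
    time: float  # ns


@dataclass
class SeedSelection:
    entries: list[SeedFrame]
    round_index: int = 0

    def __post_init__(self):
        micro = [e.microstate for e in self.entries]
        if len(micro) != len(set(micro)):
            raise ValidationError("each selected microstate may appear only once")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def select_seed_frames(dtrajs: list[DiscreteTrajectory], chi: np.ndarray,
                       active_set: np.ndarray, min_frames: int = 10,
                       betweenness_tol: float = 0.2,
                       round_index: int = 0) -> SeedSelection:
    """Select restart microstates and one representative frame for each.

    Selection is deterministic and invariant to trajectory ordering on disk:
    trajectories are scanned in sorted order of their ids.
    """
    if not dtrajs:
        raise ValidationError("no discrete trajectories given")
    chi = np.asarray(chi, dtype=float)
    order = sorted(range(len(dtrajs)), key=lambda i: dtrajs[i].trajectory_id)
    n_micro = dtrajs[0].n_microstates
    counts = np.zeros(n_micro, dtype=int)
    # best frame per microstate: (time, -inf tie-breaking by traj id then frame)
    best: dict[int, tuple] = {}
    for t in order:
        d = dtrajs[t]
        np.add.at(counts, d.states, 1)
        # last occurrence of each microstate carries its largest time here
        uniq, ridx = np.unique(d.states[::-1], return_index=True)
        last = len(d) - 1 - ridx
        for s, f in zip(uniq, last):
            time = float(f * d.dt)
            cur = best.get(int(s))
            # maximize time; ties -> lowest trajectory id, then lowest frame
            if cur is None or time > cur[0] or (
                    time == cur[0] and (d.trajectory_id, f) < (cur[1], cur[2])):
                best[int(s)] = (time, d.trajectory_id, int(f), t)
    gap = np.ones(n_micro)
    active_set = np.asarray(active_set, dtype=int)
    if chi.shape[1] >= 2:
        top2 = np.sort(chi, axis=1)[:, -2:]
        gap[active_set] = top2[:, 1] - top2[:, 0]
    entries = []
    for s in range(n_micro):
        if counts[s] == 0:
            continue
        if counts[s] == 1:
            reason = "single-frame"
        elif counts[s] < min_frames and gap[s] <= betweenness_tol:
            reason = "under-sampled-between-MS"
        else:
            continue
        time, tid, f, t = best[s]
        entries.append(SeedFrame(microstate=s, reason=reason, trajectory_id=tid,
                                 trajectory_index=t, frame_index=f, time=time))
    return SeedSelection(entries=entries, round_index=round_index)


@dataclass
class ConvergenceVerdict:
    converged: bool
    max_change: float
    per_condition: dict[str, float]


def check_convergence(prev_pi_ms: dict[str, dict], new_pi_ms: dict[str, dict],
                      tol: float = 0.05) -> ConvergenceVerdict:
    """Converged iff the biggest |change in pi_MS| over all conditions and
    matched metastable states is strictly below ``tol`` (absolute
    probability, i.e. 5 percentage points by default). Symmetric in its two
    arguments."""
    if set(prev_pi_ms) != set(new_pi_ms):
        raise ValidationError("condition labels differ between rounds")
    per_condition = {}
    for cond in prev_pi_ms:
        a, b = prev_pi_ms[cond], new_pi_ms[cond]
        if set(a) != set(b):
            raise ValidationError(
                f"metastable-state labels differ for condition {cond!r}; "
                "run MS matching across rounds first")
        per_condition[cond] = max((abs(a[m] - b[m]) for m in a), default=0.0)
    max_change = max(per_condition.values(), default=0.0)
    return ConvergenceVerdict(converged=max_change < tol,
                              max_change=max_change, per_condition=per_condition)


@dataclass
class CampaignConfig:
    """Parameters of an adaptive sampling campaign on one condition."""

    tica_lag: int = 5  # frames
    n_tica: int = 4
    n_microstates: int = 100
    msm_lag: int = 10  # frames
    n_ms: int = 3
    min_frames: int = 10
    betweenness_tol: float = 0.2
    tol: float = 0.05
    max_rounds: int = 5
    steps_per_seed: int = 300  # frames of new sampling per restart
    seed: int = 0
    threshold: float = 0.7


@dataclass
class RoundRecord:
    round_index: int
    n_trajectories: int
    n_frames: int
    pi_ms: dict[int, float]
    n_seeds: int
    seed_reasons: dict[str, int] = field(default_factory=dict)
    max_change: float | None = None


@dataclass
class CampaignReport:
    converged: bool
    rounds: list[RoundRecord]
    final_pi_ms: dict[int, float]
    trajectories: list[FeatureTrajectory]


def run_iteration_loop(trajs: list[FeatureTrajectory], config: CampaignConfig,
                       simulator, on_round=None) -> CampaignReport:
    """Iterate [estimate MSM -> select seeds -> extend -> re-estimate] until
    the equilibrium probabilities stop moving or ``max_rounds`` is reached.

    The TICA model and k-means centers are fitted once, on round 0, and new
    rounds are assigned to the same microstates so that metastable-state
    identities are stable across rounds. ``simulator`` must provide
    ``run(seed_selection, n_steps, seed) -> list[FeatureTrajectory]``.
    Reaching ``max_rounds`` yields an explicit not-converged verdict rather
    than an exception. ``on_round(round_index, dtrajs, model, partition)`` is
    an optional observer called after each round's estimation (used for
    campaign diagnostics against ground truth in tests).
    """
    trajs = list(trajs)
    tica_model = fit_tica(trajs, config.tica_lag)
    proj = [project(tica_model, t, config.n_tica) for t in trajs]
    _, centers = kmeans_discretize(proj, config.n_microstates,
                                   seed=config.seed, dt=trajs[0].dt)

    def estimate(current):
        proj = [project(tica_model, t, config.n_tica) for t in current]
        dtrajs = assign_to_centers(proj, centers, dt=current[0].dt,
                                   trajectory_ids=[t.trajectory_id for t in current])
        cm = count_matrix(dtrajs, config.msm_lag)
        model = estimate_reversible_mle(cm)
        part = coarse_grain(model, dtrajs, config.n_ms, threshold=config.threshold)
        return dtrajs, model, part

    rounds: list[RoundRecord] = []
    prev_pi: dict[int, float] | None = None
    converged = False
    for rnd in range(config.max_rounds):
        dtrajs, model, part = estimate(trajs)
        if on_round is not None:
            on_round(rnd, dtrajs, model, part)
        pi_ms = {m: float(v) for m, v in enumerate(part.pi_ms["value"])}
        record = RoundRecord(round_index=rnd, n_trajectories=len(trajs),
                             n_frames=sum(t.n_frames for t in trajs),
                             pi_ms=pi_ms, n_seeds=0)
        if prev_pi is not None:
            verdict = check_convergence({"c": prev_pi}, {"c": pi_ms}, config.tol)
            record.max_change = verdict.max_change
            if verdict.converged:
                rounds.append(record)
                converged = True
                break
        selection = select_seed_frames(dtrajs, part.chi, model.active_set,
                                       config.min_frames, config.betweenness_tol,
                                       round_index=rnd)
        record.n_seeds = len(selection)
        reasons: dict[str, int] = {}
        for e in selection:
            reasons[e.reason] = reasons.get(e.reason, 0) + 1
        record.seed_reasons = reasons
        rounds.append(record)
        prev_pi = pi_ms
        if len(selection) == 0:
            converged = True  # nothing left to seed: sampling exhaustive
            break
        new = simulator.run(selection, config.steps_per_seed,
                            seed=config.seed + 1000 * (rnd + 1))
        trajs.extend(new)
    return CampaignReport(converged=converged, rounds=rounds,
                          final_pi_ms=rounds[-1].pi_ms, trajectories=trajs)
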