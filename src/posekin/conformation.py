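"""Ensemble-weighted structural statistics per metastable state.

Structural observables (contacts, hydrogen bonds, salt-bridge and
subsegment distances) must represent the *equilibrium* ensemble, not the raw
trajectory frames. Frames are therefore drawn from the filtered metastable
frame sets with microstate probabilities taken from posterior
transition-matrix samples:

* ``draw_frames_by_ensemble`` — per replicate set (3 by default), for each of
  the 500 posterior samples, a few frames (3 by default) are drawn per MS
  with microstate weights proportional to that sample's stationary law
  restricted to the MS; statistics over replicate sets give the mean +- SD
  reported in contact tables;
* ``draw_frames_proportional`` — a fixed total (3000 by default) divided
  among the MSs proportionally to their equilibrium probabilities (largest
  remainder rounding), used for pooled distance distributions.

Within a chosen microstate frames are drawn uniformly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .coarse import MetastablePartition
from .exceptions import ValidationError
from .msm import BayesianEnsemble
from .types import ConformerEnsemble, DiscreteTrajectory

__all__ = [
    "WeightedFrameSample", "draw_frames_by_ensemble",
    "draw_frames_proportional", "ms_distance_distributions",
]


@dataclass
class WeightedFrameSample:
    """Frame references with replicate-set ids, MS labels and weights."""

    frames: pd.DataFrame  # columns: replicate, ms, microstate, traj, frame, weight
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.frames["weight"] < 0).any():
            raise ValidationError("sample weights must be >= 0")

    def __len__(self) -> int:
        return len(self.frames)


def _microstate_frame_index(partition: MetastablePartition,
                            dtrajs: list[DiscreteTrajectory]) -> dict[int, dict]:
    """Per MS: {global microstate -> (traj, frame) array}, filtered frames only."""
    out: dict[int, dict] = {}
    for m in range(partition.n_ms):
        fs = partition.frame_sets[m]
        if fs.size == 0:
            out[m] = {}
            continue
        micro = np.array([dtrajs[t].states[f] for t, f in fs])
        out[m] = {int(s): fs[micro == s] for s in np.unique(micro)}
    return out


def draw_frames_by_ensemble(ensemble: BayesianEnsemble,
                            partition: MetastablePartition,
                            dtrajs: list[DiscreteTrajectory],
                            frames_per_sample: int = 3, n_sets: int = 3,
                            seed: int = 0) -> WeightedFrameSample:
    """Replicated posterior-weighted frame draws from each MS's filtered frames.

    For each replicate set and each posterior sample, ``frames_per_sample``
    frames are drawn per metastable state: first a microstate with
    probability proportional to the sample's stationary law restricted to
    the MS's eligible microstates, then a uniform frame within it. MSs with
    no eligible frames are skipped with a warning.
    """
    import warnings

    rng = np.random.default_rng(seed)
    by_micro = _microstate_frame_index(partition, dtrajs)
    active = np.asarray(partition.active_set)
    rows = []
    for m in range(partition.n_ms):
        if not by_micro[m]:
            warnings.warn(f"metastable state {m} has no eligible frames; skipped",
                          stacklevel=2)
            continue
        micro_ids = np.array(sorted(by_micro[m]))
        local = np.searchsorted(active, micro_ids)
        for r in range(n_sets):
            for pi_s in ensemble.samples_pi:
                p = pi_s[local]
                p = p / p.sum()
                chosen = rng.choice(len(micro_ids), size=frames_per_sample, p=p)
                for c in chosen:
                    s = int(micro_ids[c])
                    frames = by_micro[m][s]
                    t, f = frames[rng.integers(len(frames))]
                    rows.append((r, m, s, int(t), int(f), 1.0))
    df = pd.DataFrame(rows, columns=["replicate", "ms", "microstate", "traj",
                                     "frame", "weight"])
    return WeightedFrameSample(frames=df, provenance={
        "mode": "by_ensemble", "n_samples": ensemble.n_samples,
        "frames_per_sample": frames_per_sample, "n_sets": n_sets, "seed": seed})


def proportional_counts(pi_ms: np.ndarray, total: int) -> np.ndarray:
    """Integer per-MS counts proportional to pi_MS, largest-remainder rounding."""
    pi_ms = np.asarray(pi_ms, dtype=float)
    exact = total * pi_ms / pi_ms.sum()
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    short = total - counts.sum()
    # distribute leftovers to the largest remainders (ties: lower MS index)
    order = sorted(range(len(pi_ms)), key=lambda i: (-remainder[i], i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def draw_frames_proportional(ensemble: BayesianEnsemble,
                             partition: MetastablePartition,
                             dtrajs: list[DiscreteTrajectory],
                             total: int = 3000, seed: int = 0
                             ) -> WeightedFrameSample:
    """One pooled draw with per-MS counts proportional to pi_MS."""
    rng = np.random.default_rng(seed)
    by_micro = _microstate_frame_index(partition, dtrajs)
    active = np.asarray(partition.active_set)
    pi_ms = np.asarray(partition.pi_ms["value"])
    counts = proportional_counts(pi_ms, total)
    pi_ref = ensemble.reference.stationary
    rows = []
    for m in range(partition.n_ms):
        if not by_micro[m]:
            continue
        micro_ids = np.array(sorted(by_micro[m]))
        local = np.searchsorted(active, micro_ids)
        p = pi_ref[local]
        p = p / p.sum()
        chosen = rng.choice(len(micro_ids), size=counts[m], p=p)
        for c in chosen:
            s = int(micro_ids[c])
            frames = by_micro[m][s]
            t, f = frames[rng.integers(len(frames))]
            rows.append((0, m, s, int(t), int(f), 1.0))
    df = pd.DataFrame(rows, columns=["replicate", "ms", "microstate", "traj",
                                     "frame", "weight"])
    return WeightedFrameSample(frames=df, provenance={
        "mode": "proportional", "total": total, "seed": seed,
        "counts": counts.tolist()})


def ms_distance_distributions(coords: ConformerEnsemble,
                              sample: WeightedFrameSample,
                              observables: dict[str, Callable[[np.ndarray], float]],
                              bins: int | np.ndarray = 30) -> dict:
    """Weighted per-MS histograms and summary statistics of observables.

    ``observables`` maps a name to a callable evaluated on each sampled
    frame's (atoms, 3) coordinates. Returns, per MS, a statistics DataFrame
    (weighted mean, SD, n) and normalized histograms; with two or more
    observables the joint values table supports paired 2-D analyses.
    """
    lookup = coords.frame_lookup()
    df = sample.frames
    values = {name: np.empty(len(df)) for name in observables}
    for row_i, (t, f) in enumerate(zip(df["traj"], df["frame"])):
        frame = coords.coordinates[lookup[(t, f)]]
        for name, fn in observables.items():
            values[name][row_i] = fn(frame)
    w = df["weight"].to_numpy(dtype=float)
    out = {}
    for m in sorted(df["ms"].unique()):
        mask = (df["ms"] == m).to_numpy()
        wm = w[mask]
        stats_rows, hists = [], {}
        for name in observables:
            v = values[name][mask]
            mean = float(np.average(v, weights=wm))
            var = float(np.average((v - mean) ** 2, weights=wm))
            stats_rows.append({"observable": name, "mean": mean,
                               "sd": float(np.sqrt(var)), "n": int(mask.sum())})
            h, edges = np.histogram(v, bins=bins, weights=wm)
            total = h.sum()
            hists[name] = (h / total if total > 0 else h, edges)
        out[int(m)] = {
            "stats": pd.DataFrame(stats_rows),
            "histograms": hists,
            "values": pd.DataFrame({name: values[name][mask] for name in observables},
                                   ).assign(weight=wm),
        }
    return out
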