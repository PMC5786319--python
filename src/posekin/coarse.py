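"""Metastable-state decomposition and kinetics on top of microstate models.

Microstates are stitched into metastable states (MSs) with PCCA++: the
leading right eigenvectors of the reversible transition matrix span a simplex
whose vertices correspond to the metastable sets; the inner-simplex vertex
construction recovers a membership matrix chi (microstate x MS, rows on the
probability simplex). Frames whose microstate has a maximum membership above
a threshold (0.7 by default) form the filtered per-MS frame sets used for
structural analysis; the rest are kept in a first-class "unassigned" pool
(the adaptive sampler consumes them).

Per-MS equilibrium probabilities aggregate the microstate stationary law
through chi; inter-MS rates are inverse mean first passage times between the
crisp microstate sets. Both carry 1-sigma intervals from a Bayesian
transition-matrix ensemble. MS identities across conditions that share one
combined discretization are matched by the number of shared crisp
microstates (ties by Jaccard index, then lower MS index).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .msm import BayesianEnsemble, TransitionModel, mfpt_from_matrix
from .types import DiscreteTrajectory

__all__ = [
    "MetastablePartition", "pcca", "assign_frames", "ms_equilibrium",
    "ms_rates", "match_ms_across_conditions", "coarse_grain",
]


def pcca(model: TransitionModel, n_ms: int) -> np.ndarray:
    """PCCA++ membership matrix chi (n_microstates x n_ms).

    Spectral clustering of the leading right eigenvectors using the
    inner-simplex vertex search; memberships are non-negative and rows sum
    to 1. Deterministic for a fixed model.
    """
    if n_ms < 1 or n_ms > model.n_states:
        raise ValidationError("n_ms must be between 1 and the number of microstates")
    lam = model.eigenvalues
    if n_ms > 1 and lam[n_ms - 1] <= 0:
        raise ValidationError(
            f"requested {n_ms} metastable states but only "
            f"{int(np.sum(lam > 0))} eigenvalues are positive; inspect the "
            "implied-timescale spectrum before choosing n_ms")
    if n_ms == 1:
        return np.ones((model.n_states, 1))
    psi = model.right_eigenvectors(n_ms)
    psi = psi / psi[0, 0] if psi[0, 0] != 0 else psi
    # inner-simplex algorithm: find n_ms rows spanning the largest simplex
    vertices = [int(np.argmax(np.linalg.norm(psi, axis=1)))]
    basis = psi - psi[vertices[0]]
    work = basis.copy()
    for _ in range(1, n_ms):
        norms = np.linalg.norm(work, axis=1)
        v = int(np.argmax(norms))
        vertices.append(v)
        direction = work[v] / norms[v]
        work = work - np.outer(work @ direction, direction)
    A = np.linalg.inv(psi[vertices])
    chi = psi @ A
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1)[:, None]
    return chi


def assign_frames(dtrajs: list[DiscreteTrajectory], chi: np.ndarray,
                  active_set: np.ndarray, threshold: float = 0.7) -> dict:
    """Split frames into per-MS sets by microstate membership.

    A frame joins MS m iff its microstate's membership row attains its
    maximum at m with value strictly above ``threshold``; frames of
    low-confidence microstates (including exact ties at the threshold) go to
    the ``"unassigned"`` pool. Each set is an integer array of
    (trajectory index, frame index) rows.
    """
    chi = np.asarray(chi, dtype=float)
    n_ms = chi.shape[1]
    n_micro = dtrajs[0].n_microstates
    ms_of_micro = -np.ones(n_micro, dtype=int)
    best = np.argmax(chi, axis=1)
    confident = chi[np.arange(len(chi)), best] > threshold
    ms_of_micro[np.asarray(active_set)[confident]] = best[confident]
    out: dict = {m: [] for m in range(n_ms)}
    out["unassigned"] = []
    for t, d in enumerate(dtrajs):
        ms = ms_of_micro[d.states]
        for m in range(n_ms):
            idx = np.flatnonzero(ms == m)
            if idx.size:
                out[m].append(np.column_stack([np.full(idx.size, t), idx]))
        idx = np.flatnonzero(ms < 0)
        if idx.size:
            out["unassigned"].append(np.column_stack([np.full(idx.size, t), idx]))
    for key in list(out):
        out[key] = (np.concatenate(out[key], axis=0) if out[key]
                    else np.empty((0, 2), dtype=int))
    return out


def ms_equilibrium(model: TransitionModel, chi: np.ndarray,
                   ensemble: BayesianEnsemble | None = None) -> dict:
    """Per-MS equilibrium probabilities pi_MS = chi^T pi, with 1-sigma
    intervals from the Bayesian ensemble when given."""
    chi = np.asarray(chi, dtype=float)
    value = chi.T @ model.stationary
    res = {"value": value}
    if ensemble is not None:
        samples = ensemble.samples_pi @ chi
        res["lower"] = np.quantile(samples, 0.15865, axis=0)
        res["upper"] = np.quantile(samples, 0.84135, axis=0)
        res["sd"] = samples.std(axis=0, ddof=1)
    return res


def ms_rates(ensemble: BayesianEnsemble, chi: np.ndarray) -> dict:
    """Pairwise MS transition rates 1/MFPT (1/ns) with 1-sigma intervals.

    MFPTs are computed on the crisp microstate sets per posterior sample;
    the maximum-likelihood model provides the reported value.
    """
    chi = np.asarray(chi, dtype=float)
    n_ms = chi.shape[1]
    if n_ms < 2:
        raise ValidationError("rates need at least 2 metastable states")
    crisp = np.argmax(chi, axis=1)
    sets = [np.flatnonzero(crisp == m) for m in range(n_ms)]
    ref = ensemble.reference
    out = {}
    for a in range(n_ms):
        for b in range(n_ms):
            if a == b or sets[a].size == 0 or sets[b].size == 0:
                continue
            t_ml = mfpt_from_matrix(ref.transition_matrix, sets[a], sets[b],
                                    dt=ref.lag_time, stationary=ref.stationary)
            samp = np.array([
                mfpt_from_matrix(P, sets[a], sets[b], dt=ref.lag_time, stationary=pi)
                for P, pi in ensemble.sample_models()])
            rates = 1.0 / samp
            out[(a, b)] = {
                "mfpt": t_ml, "rate": 1.0 / t_ml,
                "mfpt_lower": float(np.quantile(samp, 0.15865)),
                "mfpt_upper": float(np.quantile(samp, 0.84135)),
                "rate_lower": float(np.quantile(rates, 0.15865)),
                "rate_upper": float(np.quantile(rates, 0.84135)),
            }
    return out


@dataclass
class MetastablePartition:
    """PCCA++ partition of one condition's microstates with kinetics."""

    chi: np.ndarray  # (n_active_microstates, n_ms)
    active_set: np.ndarray  # global microstate ids the rows of chi refer to
    crisp: np.ndarray  # argmax assignment per active microstate
    pi_ms: dict  # value / lower / upper / sd
    rates: dict  # (a, b) -> rate & mfpt with intervals; empty if n_ms < 2
    frame_sets: dict  # per-MS (traj, frame) arrays + "unassigned"
    condition: str = ""
    threshold: float = 0.7

    def __post_init__(self):
        chi = self.chi
        if np.any(chi < 0) or np.any(chi > 1 + 1e-12):
            raise ValidationError("memberships must lie in [0, 1]")
        if np.max(np.abs(chi.sum(axis=1) - 1.0)) > 1e-9:
            raise ValidationError("membership rows must sum to 1 within 1e-9")
        if abs(float(np.sum(self.pi_ms["value"])) - 1.0) > 1e-9:
            raise ValidationError("pi_MS must sum to 1 within 1e-9")

    @property
    def n_ms(self) -> int:
        return self.chi.shape[1]

    def crisp_sets_global(self) -> list[np.ndarray]:
        return [np.asarray(self.active_set)[self.crisp == m]
                for m in range(self.n_ms)]


def coarse_grain(model: TransitionModel, dtrajs: list[DiscreteTrajectory],
                 n_ms: int, ensemble: BayesianEnsemble | None = None,
                 threshold: float = 0.7, condition: str = "") -> MetastablePartition:
    """Convenience wrapper: PCCA++ + frame filtering + pi_MS + rates."""
    chi = pcca(model, n_ms)
    frame_sets = assign_frames(dtrajs, chi, model.active_set, threshold)
    pi_ms = ms_equilibrium(model, chi, ensemble)
    rates = {}
    if ensemble is not None and n_ms >= 2:
        rates = ms_rates(ensemble, chi)
    return MetastablePartition(chi=chi, active_set=np.asarray(model.active_set),
                               crisp=np.argmax(chi, axis=1), pi_ms=pi_ms,
                               rates=rates, frame_sets=frame_sets,
                               condition=condition, threshold=threshold)


def match_ms_across_conditions(partitions: dict[str, MetastablePartition]) -> dict:
    """Match MS identities across conditions sharing one discretization.

    Greedy maximum-overlap matching on the count of shared crisp microstates
    (ties broken by larger Jaccard index, then lower MS index); unmatched
    states receive fresh labels. Returns {condition: {local MS -> global label}}.
    """
    labels = sorted(partitions)
    spaces = [frozenset(np.asarray(partitions[c].active_set).tolist()) for c in labels]
    if len(labels) > 1 and all(spaces[0].isdisjoint(s) for s in spaces[1:]):
        raise ValidationError("partitions live on disjoint microstate spaces; "
                              "they must share the combined discretization")
    mapping: dict[str, dict[int, int]] = {}
    global_sets: dict[int, set] = {}
    next_label = 0
    for c in labels:
        part = partitions[c]
        sets = [set(s.tolist()) for s in part.crisp_sets_global()]
        local_map: dict[int, int] = {}
        taken: set[int] = set()
        # score all (local, global) pairs, then greedy
        pairs = []
        for m, s in enumerate(sets):
            for g, gs in global_sets.items():
                overlap = len(s & gs)
                if overlap > 0:
                    jac = overlap / len(s | gs)
                    pairs.append((overlap, jac, -m, -g, m, g))
        for overlap, jac, _, _, m, g in sorted(pairs, reverse=True):
            if m in local_map or g in taken:
                continue
            local_map[m] = g
            taken.add(g)
        for m, s in enumerate(sets):
            if m not in local_map:
                local_map[m] = next_label
                global_sets[next_label] = set()
                next_label = max(global_sets) + 1 if global_sets else next_label + 1
            # refresh the global prototype with this condition's microstates
            global_sets.setdefault(local_map[m], set()).update(s)
        mapping[c] = local_map
        next_label = max(global_sets, default=-1) + 1
    return mapping
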