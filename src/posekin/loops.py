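"""Clustering of flexible-loop conformations by pairwise RMSD.

The flexible N-terminal segment of a receptor adopts many conformations;
clustering them needs a residue set stable enough for superposition. That
set is found by iteratively excluding residues with high root mean squared
fluctuation (RMSF > 5.0 A by default) after least-squares superposition on
the current set, until no residue is dropped. Pairwise RMSDs over the
retained residues' backbone atoms (after per-pair optimal superposition,
Kabsch) feed Ward hierarchical clustering; the cluster count is the smallest
one for which every cluster either has mean intra-cluster pairwise RMSD
within a limit (5.0 A) or holds less than a small fraction (5%) of the
frames. Cluster populations are finally re-weighted by the equilibrium
probabilities of the metastable states their member frames belong to.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy
from scipy.spatial.distance import squareform

from .exceptions import ValidationError
from .types import ConformerEnsemble

__all__ = [
    "superpose", "iterative_rmsf_filter", "pairwise_rmsd_matrix",
    "ward_cluster_cut", "reweight_populations", "representative_frames",
    "LoopClusterResult", "cluster_loop_conformations",
]

_BACKBONE = ["N", "CA", "C", "O"]


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares (Kabsch) superposition of one structure onto another."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    H = mc.T @ rc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    return mc @ R + reference.mean(axis=0)


def _loop_coords(ensemble: ConformerEnsemble, residues,
                 atom_policy: str = "backbone") -> tuple[np.ndarray, np.ndarray]:
    """(frames, atoms, 3) coordinates of the selected residues + residue id per atom."""
    residues = list(residues)
    if atom_policy == "backbone":
        idx = ensemble.atom_indices(residue_ids=residues, atom_names=_BACKBONE)
    else:
        idx = ensemble.atom_indices(residue_ids=residues, heavy_only=True)
    if idx.size == 0:
        raise ValidationError("selected residues resolve to no atoms")
    rid = ensemble.atoms["residue_id"].to_numpy()[idx]
    return ensemble.coordinates[:, idx], rid


def iterative_rmsf_filter(ensemble: ConformerEnsemble, residues,
                          rmsf_cutoff: float = 5.0,
                          atom_policy: str = "backbone"
                          ) -> tuple[list[int], list[list[int]]]:
    """Iteratively drop residues whose RMSF exceeds the cutoff.

    Each pass superimposes every frame on the mean structure over the current
    residue set (two alignment refinements), computes per-residue RMSF about
    the mean (mean over the residue's atoms of the atomic RMSF), and drops
    residues above the cutoff; it stops when no residue is dropped. Returns
    the retained residues and the per-pass exclusion history.
    """
    if ensemble.n_frames < 2:
        raise ValidationError("RMSF needs at least 2 frames")
    current = sorted(set(residues))
    history: list[list[int]] = []
    while True:
        if len(current) < 3:
            raise ValidationError(
                "fewer than 3 residues remain; superposition is ill-posed")
        X, rid = _loop_coords(ensemble, current, atom_policy)
        ref = X[0]
        for _ in range(2):  # align to running mean, twice
            aligned = np.stack([superpose(x, ref) for x in X])
            ref = aligned.mean(axis=0)
        fluct = np.sqrt(((aligned - ref) ** 2).sum(axis=2).mean(axis=0))  # per atom
        res_rmsf = {r: float(fluct[rid == r].mean()) for r in current}
        dropped = [r for r in current if res_rmsf[r] > rmsf_cutoff]
        history.append(dropped)
        if not dropped:
            return current, history
        current = [r for r in current if r not in dropped]


def pairwise_rmsd_matrix(ensemble: ConformerEnsemble, residues,
                         atom_policy: str = "backbone") -> np.ndarray:
    """Symmetric matrix of minimal (superposed) RMSDs between all frame pairs.

    Each pair is optimally superimposed on the selected residues' atoms
    before the RMSD is taken over the same atoms (batched Kabsch via SVD).
    """
    X, _ = _loop_coords(ensemble, residues, atom_policy)
    F, A, _ = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    sq = (Xc ** 2).sum(axis=(1, 2))
    out = np.zeros((F, F))
    for i in range(F):
        H = np.einsum("ak,fal->fkl", Xc[i], Xc[i + 1:])
        if H.shape[0] == 0:
            continue
        U, S, Vt = np.linalg.svd(H)
        det = np.linalg.det(U @ Vt)
        S[:, -1] *= np.sign(det)
        msd = (sq[i] + sq[i + 1:] - 2.0 * S.sum(axis=1)) / A
        out[i, i + 1:] = out[i + 1:, i] = np.sqrt(np.maximum(msd, 0.0))
    return out


def ward_cluster_cut(rmsd_matrix: np.ndarray, rmsd_limit: float = 5.0,
                     small_cluster_frac: float = 0.05) -> np.ndarray:
    """Ward clustering with the smallest cluster count satisfying the rule.

    The number of clusters is the smallest k such that every cluster has mean
    intra-cluster pairwise RMSD <= ``rmsd_limit`` *or* holds less than
    ``small_cluster_frac`` of all frames. Labels are contiguous from 0,
    ordered by decreasing cluster size (ties by first frame index).
    """
    D = np.asarray(rmsd_matrix, dtype=float)
    F = D.shape[0]
    if D.shape != (F, F) or np.max(np.abs(D - D.T)) > 1e-8:
        raise ValidationError("RMSD matrix must be square and symmetric")
    if np.allclose(D, 0.0):
        return np.zeros(F, dtype=int)
    Z = scipy.cluster.hierarchy.ward(squareform(D, checks=False))
    for k in range(1, F + 1):
        labels = scipy.cluster.hierarchy.fcluster(Z, k, criterion="maxclust")
        ok = True
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            if members.size < small_cluster_frac * F:
                continue
            if members.size == 1:
                continue
            sub = D[np.ix_(members, members)]
            mean_rmsd = sub[np.triu_indices(members.size, k=1)].mean()
            if mean_rmsd > rmsd_limit:
                ok = False
                break
        if ok:
            return _canonical_labels(labels)
    return _canonical_labels(labels)  # pragma: no cover - loop always returns


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0.. by decreasing size, ties by first occurrence."""
    uniq, counts = np.unique(labels, return_counts=True)
    first = np.array([np.argmax(labels == u) for u in uniq])
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], first[i]))
    remap = {uniq[i]: rank for rank, i in enumerate(order)}
    return np.array([remap[v] for v in labels], dtype=int)


def reweight_populations(labels: np.ndarray, frame_ms: np.ndarray,
                         pi_ms: dict | np.ndarray) -> np.ndarray:
    """Cluster populations (%) re-weighted by metastable-state probabilities.

    Each frame carries weight pi_MS(its MS) / (number of sampled frames from
    that MS), so every MS contributes in proportion to its equilibrium
    probability regardless of how many frames were drawn from it.
    """
    labels = np.asarray(labels)
    frame_ms = np.asarray(frame_ms)
    if labels.shape != frame_ms.shape:
        raise ValidationError("labels and frame->MS map must have equal length")
    pi = dict(enumerate(pi_ms)) if not isinstance(pi_ms, dict) else pi_ms
    for m in np.unique(frame_ms):
        if m not in pi:
            raise ValidationError(f"frame mapped to MS {m} with unknown pi_MS")
    counts = {m: int((frame_ms == m).sum()) for m in np.unique(frame_ms)}
    w = np.array([pi[m] / counts[m] for m in frame_ms], dtype=float)
    n_clusters = labels.max() + 1
    pops = np.array([w[labels == c].sum() for c in range(n_clusters)])
    return 100.0 * pops / pops.sum()


def representative_frames(rmsd_matrix: np.ndarray, labels: np.ndarray,
                          n: int = 5) -> dict[int, np.ndarray]:
    """Per cluster: the medoid frame plus its n-1 nearest neighbours."""
    out = {}
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        sub = rmsd_matrix[np.ix_(members, members)]
        medoid = members[np.argmin(sub.sum(axis=1))]
        order = members[np.argsort(rmsd_matrix[medoid, members], kind="stable")]
        out[int(c)] = order[:n]
    return out


@dataclass
class LoopClusterResult:
    retained_residues: list[int]
    labels: np.ndarray
    raw_populations: np.ndarray  # %
    reweighted_populations: np.ndarray  # %
    intra_cluster_rmsd: np.ndarray  # A, mean pairwise per cluster
    representatives: dict[int, np.ndarray] = field(default_factory=dict)
    exclusion_history: list[list[int]] = field(default_factory=list)

    def __post_init__(self):
        if abs(self.reweighted_populations.sum() - 100.0) > 1e-6:
            raise ValidationError("reweighted populations must sum to 100%")


def cluster_loop_conformations(ensemble: ConformerEnsemble, residues,
                               frame_ms: np.ndarray | None = None,
                               pi_ms: dict | np.ndarray | None = None,
                               rmsf_cutoff: float = 5.0, rmsd_limit: float = 5.0,
                               small_cluster_frac: float = 0.05,
                               skip_rmsf_filter: bool = False,
                               atom_policy: str = "backbone") -> LoopClusterResult:
    """Full loop-clustering stage: RMSF filter -> RMSD matrix -> Ward cut ->
    (optionally) MS-probability reweighting.

    ``skip_rmsf_filter=True`` accepts ``residues`` as the final selection
    directly, the mode used when the retained ranges are known a priori.
    """
    if skip_rmsf_filter:
        retained, history = sorted(set(residues)), []
    else:
        retained, history = iterative_rmsf_filter(ensemble, residues,
                                                  rmsf_cutoff, atom_policy)
    D = pairwise_rmsd_matrix(ensemble, retained, atom_policy)
    labels = ward_cluster_cut(D, rmsd_limit, small_cluster_frac)
    n_clusters = labels.max() + 1
    raw = np.array([100.0 * (labels == c).mean() for c in range(n_clusters)])
    if frame_ms is not None and pi_ms is not None:
        rew = reweight_populations(labels, frame_ms, pi_ms)
    else:
        rew = raw.copy()
    intra = np.zeros(n_clusters)
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        if members.size > 1:
            sub = D[np.ix_(members, members)]
            intra[c] = sub[np.triu_indices(members.size, k=1)].mean()
    return LoopClusterResult(retained_residues=retained, labels=labels,
                             raw_populations=raw, reweighted_populations=rew,
                             intra_cluster_rmsd=intra,
                             representatives=representative_frames(D, labels),
                             exclusion_history=history)
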