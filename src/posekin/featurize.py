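"""Binding-mode features and distance/contact observables from coordinates.

The MSM input features describe the pose of a bitopic ligand inside a
receptor's binding sites through simple geometric measures:

* distances from the ligand's (four) nitrogen atoms to the Cbeta atoms of
  nearby residues — a residue qualifies if its Cbeta lies within a cutoff
  (7.0 A by default, boundary inclusive) of any nitrogen in a designated
  reference frame;
* intramolecular distances that pin the orientation of the secondary
  pharmacophore (by default N4-N3 and N4-amide O);
* the signed projections of the vectors from each aromatic-ring center of
  mass to a reference atom (N4) onto the membrane normal, capturing the
  ring's tilt relative to the membrane plane.

With 12 qualifying Cbeta-nitrogen pairs this recipe yields 16 features.

The same module provides the ensemble observables used downstream:
minimum group-group distances (salt bridges), weighted contact frequencies
with replicate-set statistics, hydrogen-bond frequencies (geometric or
distance-only criterion), and distances between the unweighted centers of
mass of helical subsegments.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .exceptions import ValidationError
from .types import ATOMIC_MASSES, ConformerEnsemble, FeatureTrajectory, SubsegmentDef

__all__ = [
    "FeatureSpec", "select_feature_residues", "compute_feature_matrix",
    "min_group_distance", "contact_frequencies", "hbond_frequency",
    "subsegment_com_distance",
]

LISTING_THRESHOLD = 0.25  # contact frequency above which a residue is listed
DISPLAY_THRESHOLD = 0.65  # contact frequency above which it is displayed


@dataclass
class FeatureSpec:
    """Recipe for the binding-mode feature vector."""

    ligand_nitrogens: list[str] = field(default_factory=lambda: ["N1", "N2", "N3", "N4"])
    candidate_residues: list[int] = field(default_factory=list)
    selection_cutoff: float = 7.0  # A, boundary inclusive
    intramolecular_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("N4", "N3"), ("N4", "O1")])
    ring_definitions: dict[str, list[str]] = field(default_factory=dict)
    ring_reference_atom: str = "N4"
    membrane_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.membrane_normal = np.asarray(self.membrane_normal, dtype=float)
        if self.selection_cutoff <= 0:
            raise ValidationError("selection_cutoff must be > 0")
        if abs(np.linalg.norm(self.membrane_normal) - 1.0) > 1e-9:
            raise ValidationError("membrane_normal must have unit length within 1e-9")
        for name, members in self.ring_definitions.items():
            if len(members) < 3:
                raise ValidationError(f"ring {name!r} has fewer than 3 member atoms")


def _ligand_atom_index(ensemble: ConformerEnsemble, name: str) -> int:
    idx = ensemble.atom_indices(atom_names=name, segment="ligand")
    if idx.size == 0:
        idx = ensemble.atom_indices(atom_names=name)
    if idx.size == 0:
        raise ValidationError(f"ligand atom {name!r} not found")
    return int(idx[0])


def select_feature_residues(reference: ConformerEnsemble, spec: FeatureSpec,
                            frame_index: int = 0) -> list[tuple[str, int]]:
    """Residues whose Cbeta lies within the cutoff of a ligand nitrogen.

    Evaluated in one designated reference frame. A pair (nitrogen, residue)
    is included iff distance(Cbeta, N) <= cutoff; output is ordered by
    residue index then nitrogen index, so feature columns are deterministic.
    """
    coords = reference.coordinates[frame_index]
    n_idx = [_ligand_atom_index(reference, n) for n in spec.ligand_nitrogens]
    pairs = []
    for rid in spec.candidate_residues:
        cb = reference.atom_indices(residue_ids=rid, atom_names="CB")
        if cb.size == 0:
            raise ValidationError(f"residue {rid} has no Cbeta atom")
        d = np.linalg.norm(coords[n_idx] - coords[cb[0]], axis=1)
        for j, nitro in enumerate(spec.ligand_nitrogens):
            if d[j] <= spec.selection_cutoff:
                pairs.append((nitro, int(rid)))
    pairs.sort(key=lambda p: (p[1], spec.ligand_nitrogens.index(p[0])))
    return pairs


def compute_feature_matrix(traj: ConformerEnsemble, pairs: list[tuple[str, int]],
                           spec: FeatureSpec, dt: float = 1.0,
                           trajectory_id: str = "traj000") -> FeatureTrajectory:
    """Evaluate the feature recipe on every frame of a coordinate trajectory.

    Column order: Cbeta-N distances (as selected), intramolecular distances,
    then one signed ring projection per ring definition. Ring centers of mass
    are unweighted means over member heavy atoms.
    """
    if not pairs and not spec.intramolecular_pairs and not spec.ring_definitions:
        raise ValidationError("no features requested")
    X = traj.coordinates
    cols, names = [], []
    for nitro, rid in pairs:
        ni = _ligand_atom_index(traj, nitro)
        cb = traj.atom_indices(residue_ids=rid, atom_names="CB")
        if cb.size == 0:
            raise ValidationError(f"residue {rid} has no Cbeta atom")
        cols.append(np.linalg.norm(X[:, ni] - X[:, cb[0]], axis=1))
        names.append(f"d_CB{rid}_{nitro}")
    for a, b in spec.intramolecular_pairs:
        ia, ib = _ligand_atom_index(traj, a), _ligand_atom_index(traj, b)
        cols.append(np.linalg.norm(X[:, ia] - X[:, ib], axis=1))
        names.append(f"d_{a}_{b}")
    if spec.ring_definitions:
        ref = _ligand_atom_index(traj, spec.ring_reference_atom)
        heavy = set(traj.atom_indices(heavy_only=True).tolist())
        for ring_name, members in spec.ring_definitions.items():
            idx = [_ligand_atom_index(traj, m) for m in members]
            idx = [i for i in idx if i in heavy]
            if len(idx) < 3:
                raise ValidationError(f"ring {ring_name!r} has fewer than 3 heavy atoms")
            com = X[:, idx].mean(axis=1)
            cols.append((X[:, ref] - com) @ spec.membrane_normal)
            names.append(f"proj_{ring_name}_{spec.ring_reference_atom}")
    return FeatureTrajectory(values=np.column_stack(cols), feature_names=names,
                             dt=dt, trajectory_id=trajectory_id)


def min_group_distance(frame: np.ndarray, group_a, group_b) -> float:
    """Minimum Euclidean distance (A) over all cross pairs of two atom sets."""
    group_a = np.atleast_1d(np.asarray(group_a, dtype=int))
    group_b = np.atleast_1d(np.asarray(group_b, dtype=int))
    if group_a.size == 0 or group_b.size == 0:
        raise ValidationError("both atom groups must be nonempty")
    return float(cdist(frame[group_a], frame[group_b]).min())


def _frame_weights(ensemble: ConformerEnsemble) -> np.ndarray:
    if "weight" in ensemble.frames:
        w = ensemble.frames["weight"].to_numpy(dtype=float)
    else:
        w = np.ones(ensemble.n_frames)
    if w.sum() == 0:
        raise ValidationError("all frame weights are zero")
    return w


def contact_frequencies(frames: ConformerEnsemble, ligand_atoms,
                        protein_residues, cutoff: float = 5.0) -> pd.DataFrame:
    """Per-residue ligand contact frequencies with replicate-set statistics.

    For each replicate set (the ``replicate`` frame column; a single implicit
    set otherwise), the frequency of a residue is the weighted fraction of
    frames in which its minimum heavy-atom distance to the ligand is within
    the cutoff. Reported as mean and SD over replicate sets, with boolean
    flags for the listing (> 25%) and display (> 65%) thresholds.
    """
    ligand_atoms = np.atleast_1d(np.asarray(ligand_atoms, dtype=int))
    heavy = frames.atoms["is_heavy"].to_numpy() if "is_heavy" in frames.atoms \
        else np.ones(frames.n_atoms, dtype=bool)
    lig = ligand_atoms[heavy[ligand_atoms]]
    if lig.size == 0:
        raise ValidationError("ligand selection has no heavy atoms")
    w = _frame_weights(frames)
    reps = frames.frames["replicate"].to_numpy() if "replicate" in frames.frames \
        else np.zeros(frames.n_frames, dtype=int)
    rep_ids = np.unique(reps)
    rows = []
    for rid in protein_residues:
        res_idx = frames.atom_indices(residue_ids=rid, heavy_only=True)
        if res_idx.size == 0:
            raise ValidationError(f"residue {rid} has no heavy atoms")
        mind = np.array([cdist(frames.coordinates[f][lig],
                               frames.coordinates[f][res_idx]).min()
                         for f in range(frames.n_frames)])
        hit = mind <= cutoff
        freqs = []
        for r in rep_ids:
            m = reps == r
            if w[m].sum() == 0:
                raise ValidationError(f"replicate set {r} has zero total weight")
            freqs.append(float((w[m] * hit[m]).sum() / w[m].sum()))
        freqs = np.asarray(freqs)
        mean = float(freqs.mean())
        rows.append({"residue_id": rid, "mean": mean,
                     "sd": float(freqs.std(ddof=1)) if len(freqs) > 1 else 0.0,
                     "listed": mean > LISTING_THRESHOLD,
                     "display": mean > DISPLAY_THRESHOLD})
    return pd.DataFrame(rows)


def hbond_frequency(frames: ConformerEnsemble, donor, acceptor,
                    criterion: str = "distance_angle",
                    distance_cutoff: float = 3.5,
                    angle_cutoff: float = 120.0) -> float:
    """Weighted fraction of frames satisfying a hydrogen-bond criterion.

    ``criterion='distance_angle'``: donor-acceptor heavy-atom distance <=
    ``distance_cutoff`` (A) and donor-H...acceptor angle >= ``angle_cutoff``
    (degrees); ``donor`` is then (heavy index, hydrogen index).
    ``criterion='distance_only'``: minimum heavy-atom distance between the
    donor and acceptor groups <= cutoff.
    """
    w = _frame_weights(frames)
    X = frames.coordinates
    acceptor = np.atleast_1d(np.asarray(acceptor, dtype=int))
    if criterion == "distance_only":
        donor_g = np.atleast_1d(np.asarray(donor, dtype=int))
        hit = np.array([cdist(X[f][donor_g], X[f][acceptor]).min() <= distance_cutoff
                        for f in range(frames.n_frames)])
    elif criterion == "distance_angle":
        try:
            d_heavy, d_h = int(donor[0]), int(donor[1])
        except (TypeError, IndexError):
            raise ValidationError(
                "distance_angle criterion needs donor = (heavy index, H index)")
        # nearest acceptor per frame defines the geometry
        d_all = np.linalg.norm(X[:, acceptor] - X[:, d_heavy][:, None], axis=2)
        nearest = acceptor[np.argmin(d_all, axis=1)]
        dist_ok = d_all.min(axis=1) <= distance_cutoff
        v1 = X[:, d_heavy] - X[np.arange(frames.n_frames), d_h]
        v2 = X[np.arange(frames.n_frames), nearest] - X[np.arange(frames.n_frames), d_h]
        cosang = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        hit = dist_ok & (ang >= angle_cutoff)
    else:
        raise ValidationError(f"unknown H-bond criterion {criterion!r}")
    return float((w * hit).sum() / w.sum())


def subsegment_com_distance(frame: np.ndarray, atoms: pd.DataFrame,
                            subsegments: tuple[SubsegmentDef, SubsegmentDef],
                            mass_weighted: bool = False) -> float:
    """Distance (A) between the centers of mass of two helical subsegments.

    COMs are unweighted means over heavy atoms by default; mass weighting is
    optional and flagged by the caller in its outputs.
    """
    coms = []
    for seg in subsegments:
        mask = atoms["residue_id"].isin(seg.residue_ids).to_numpy()
        if "is_heavy" in atoms:
            mask &= atoms["is_heavy"].to_numpy()
        if seg.atom_policy == "backbone":
            mask &= atoms["atom_name"].isin(["N", "CA", "C", "O"]).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValidationError(f"subsegment {seg.name!r} resolves to no atoms")
        if mass_weighted:
            masses = np.array([ATOMIC_MASSES.get(e, 12.011)
                               for e in atoms["element"].to_numpy()[idx]])
            coms.append((frame[idx] * masses[:, None]).sum(axis=0) / masses.sum())
        else:
            coms.append(frame[idx].mean(axis=0))
    return float(np.linalg.norm(coms[0] - coms[1]))
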