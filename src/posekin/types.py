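"""Shared in-memory containers for trajectories, features and conformer sets.

Units follow one convention throughout the package: coordinates and distances
in angstrom (A), times in nanoseconds (ns), frames 0-indexed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "FeatureTrajectory",
    "ConformerEnsemble",
    "DiscreteTrajectory",
    "SubsegmentDef",
    "ATOMIC_MASSES",
]

# minimal mass table; pseudo-atoms default to carbon
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                 "S": 32.06, "P": 30.974}


@dataclass
class FeatureTrajectory:
    """Per-frame feature vectors (frames x features, in A) at a fixed time step."""

    values: np.ndarray
    feature_names: list[str]
    dt: float  # ns per frame
    trajectory_id: str = "traj000"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("feature values must be a 2-D frames x features array")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValidationError(
                f"feature_names length {len(self.feature_names)} does not match "
                f"column count {self.values.shape[1]}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values contain missing/non-finite entries")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ConformerEnsemble:
    """Labelled 3-D coordinate frames sharing one atom table.

    ``coordinates`` has shape (frames, atoms, 3) in A. ``atoms`` carries one
    row per atom with at least columns ``residue_id``, ``atom_name``,
    ``element`` and ``is_heavy``; ``frames`` carries one row per frame with at
    least ``traj`` and ``frame`` and optionally ``state`` (hidden or
    metastable label) and ``weight``.
    """

    coordinates: np.ndarray
    atoms: pd.DataFrame
    frames: pd.DataFrame

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValidationError("coordinates must have shape (frames, atoms, 3)")
        if len(self.atoms) != self.coordinates.shape[1]:
            raise ValidationError("atom table length must equal the atom count of every frame")
        if len(self.frames) != self.coordinates.shape[0]:
            raise ValidationError("frame table length must equal the frame count")
        if "weight" in self.frames and (np.asarray(self.frames["weight"]) < 0).any():
            raise ValidationError("frame weights must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def atom_indices(self, *, residue_ids=None, atom_names=None, segment=None,
                     heavy_only: bool = False) -> np.ndarray:
        """Indices of atoms matching all given criteria, in table order."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residue_ids is not None:
            mask &= self.atoms["residue_id"].isin(np.atleast_1d(residue_ids)).to_numpy()
        if atom_names is not None:
            names = [atom_names] if isinstance(atom_names, str) else list(atom_names)
            mask &= self.atoms["atom_name"].isin(names).to_numpy()
        if segment is not None and "segment" in self.atoms:
            mask &= (self.atoms["segment"] == segment).to_numpy()
        if heavy_only and "is_heavy" in self.atoms:
            mask &= self.atoms["is_heavy"].to_numpy()
        return np.flatnonzero(mask)

    def subset_frames(self, frame_indices) -> "ConformerEnsemble":
        idx = np.asarray(frame_indices, dtype=int)
        return ConformerEnsemble(
            coordinates=self.coordinates[idx],
            atoms=self.atoms,
            frames=self.frames.iloc[idx].reset_index(drop=True),
        )

    def frame_lookup(self) -> dict[tuple, int]:
        """Map (traj, frame) -> global frame index."""
        return {(t, f): i for i, (t, f) in
                enumerate(zip(self.frames["traj"], self.frames["frame"]))}


@dataclass
class DiscreteTrajectory:
    """Per-frame microstate indices after k-means discretization."""

    states: np.ndarray
    n_microstates: int
    dt: float  # ns
    trajectory_id: str = "traj000"
    condition: str = ""

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1 or self.states.size < 1:
            raise ValidationError("a discrete trajectory needs at least one frame")
        if self.states.min() < 0 or self.states.max() >= self.n_microstates:
            raise ValidationError(
                f"state indices must lie in [0, {self.n_microstates})")

    def __len__(self) -> int:
        return self.states.size


@dataclass
class SubsegmentDef:
    """A named helical subsegment: a residue range plus an atom policy."""

    name: str
    residue_ids: list[int] = field(default_factory=list)
    atom_policy: str = "heavy"  # "heavy" | "backbone"

    def __post_init__(self):
        if len(self.residue_ids) == 0:
            raise ValidationError(f"subsegment {self.name!r} has an empty residue range")
        if self.atom_policy not in ("heavy", "backbone"):
            raise ValidationError("atom_policy must be 'heavy' or 'backbone'")
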