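"""File I/O: feature tables, discrete trajectories, partitions, coordinates.

Feature trajectories round-trip through columnar CSV (header = feature
names); discrete trajectories through plain integer text files (one
microstate per line), interoperable with common MSM toolchains; partitions
and run summaries through JSON. Coordinate trajectories (PDB topology plus
DCD/XTC frames) are read through mdtraj when it is available.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coarse import MetastablePartition
from .types import ConformerEnsemble, DiscreteTrajectory, FeatureTrajectory

__all__ = [
    "write_feature_csv", "read_feature_csv", "write_dtraj", "read_dtraj",
    "partition_to_json", "load_coordinate_trajectory",
]


def write_feature_csv(traj: FeatureTrajectory, path) -> None:
    df = pd.DataFrame(traj.values, columns=traj.feature_names)
    df.insert(0, "time_ns", np.arange(traj.n_frames) * traj.dt)
    df.to_csv(path, index=False)


def read_feature_csv(path, trajectory_id: str | None = None) -> FeatureTrajectory:
    df = pd.read_csv(path)
    t = df.pop("time_ns").to_numpy()
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    return FeatureTrajectory(values=df.to_numpy(), feature_names=list(df.columns),
                             dt=dt, trajectory_id=trajectory_id or Path(path).stem)


def write_dtraj(dtraj: DiscreteTrajectory, path) -> None:
    np.savetxt(path, dtraj.states, fmt="%d")


def read_dtraj(path, n_microstates: int, dt: float = 1.0,
               condition: str = "") -> DiscreteTrajectory:
    states = np.loadtxt(path, dtype=int, ndmin=1)
    return DiscreteTrajectory(states=states, n_microstates=n_microstates, dt=dt,
                              trajectory_id=Path(path).stem, condition=condition)


def partition_to_json(partition: MetastablePartition, path) -> None:
    """Human-readable partition report: memberships, pi with 1-sigma bounds,
    rates per ordered state pair."""
    pi = partition.pi_ms
    doc = {
        "condition": partition.condition,
        "threshold": partition.threshold,
        "active_set": np.asarray(partition.active_set).tolist(),
        "memberships": np.asarray(partition.chi).tolist(),
        "crisp": np.asarray(partition.crisp).tolist(),
        "pi_ms": {"value": np.asarray(pi["value"]).tolist(),
                  **{k: np.asarray(pi[k]).tolist()
                     for k in ("lower", "upper", "sd") if k in pi}},
        "rates_per_ns": {f"{a}->{b}": r for (a, b), r in partition.rates.items()},
        "n_unassigned_frames": int(len(partition.frame_sets["unassigned"])),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_coordinate_trajectory(topology, trajectories) -> ConformerEnsemble:
    """Read a PDB topology plus DCD/XTC coordinate files into a ConformerEnsemble.

    Coordinates are converted from mdtraj's nm to A. Frames are labelled with
    the source file index and frame number.
    """
    import mdtraj as md

    top = md.load_topology(str(topology))
    atoms = pd.DataFrame([{
        "segment": a.segment_id or a.residue.chain.index,
        "residue_id": a.residue.resSeq,
        "residue_name": a.residue.name,
        "atom_name": a.name,
        "element": a.element.symbol if a.element else "C",
    } for a in top.atoms])
    atoms["is_heavy"] = atoms["element"] != "H"
    coords, frames = [], []
    paths = [trajectories] if isinstance(trajectories, (str, Path)) else list(trajectories)
    for k, p in enumerate(paths):
        t = md.load(str(p), top=top) if not str(p).endswith(".pdb") else md.load(str(p))
        coords.append(t.xyz * 10.0)  # nm -> A
        frames.append(pd.DataFrame({"traj": k, "frame": np.arange(t.n_frames)}))
    return ConformerEnsemble(coordinates=np.concatenate(coords, axis=0),
                             atoms=atoms, frames=pd.concat(frames, ignore_index=True))
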