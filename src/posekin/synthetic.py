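"""Ground-truth surrogate data for the binding-pose kinetics pipeline.

Real studies of this kind analyse hundreds of MD trajectories that are far too
large to ship; every downstream stage of this package is therefore exercised
on synthetic data with the statistical structure the analysis assumes:

* hidden metastable-state dynamics follow a discrete-time reversible Markov
  chain with designed stationary distribution and exchange probabilities,
  so equilibrium probabilities and mean first passage times have exact
  linear-algebra ground truth;
* observed features are diagonal-covariance Gaussian emissions around
  state-specific mean vectors in a 16-dimensional "binding-mode feature"
  space (ligand-protein distances, intramolecular distances, ring-normal
  projections);
* toy 3-D coordinate ensembles (a flexible pseudo-loop, four pseudo-helical
  subsegments carrying Cbeta atoms, and a pseudo-ligand with four nitrogens,
  an amide oxygen and two rings) feed the contact, subsegment-distance and
  loop-clustering stages.

One global seed fans out to per-trajectory substreams so that the trajectory
count can grow without reshuffling existing trajectories.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .types import ConformerEnsemble, FeatureTrajectory

__all__ = [
    "ToySystemSpec",
    "ToyStructureSpec",
    "metropolis_exchange",
    "default_system_spec",
    "default_structure_spec",
    "simulate_hidden_chain",
    "emit_features",
    "emit_coordinates",
    "chain_mfpt",
    "SyntheticSimulator",
]

_CHAIN_STREAM, _FEATURE_STREAM, _COORD_STREAM = 11, 13, 17


def _substream(seed: int, stream: int, index: int) -> np.random.Generator:
    """Independent, reproducible substream for one trajectory of one kind."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, int(index)]))


@dataclass
class ToySystemSpec:
    """Designed metastable-state-switching system with Gaussian emissions.

    ``stationary`` is the designed equilibrium distribution and ``exchange``
    the per-step jump probability matrix (row-stochastic, in detailed balance
    with ``stationary``). ``emission_means`` has one row of feature means per
    state (A); ``emission_sd`` is a scalar or per-feature vector (A).
    """

    n_states: int
    stationary: np.ndarray
    exchange: np.ndarray
    n_traj: int = 40
    n_steps: int = 5000
    dt: float = 0.3  # ns per frame
    emission_means: np.ndarray | None = None
    emission_sd: float | np.ndarray = 0.5
    seed: int = 0

    def __post_init__(self):
        self.stationary = np.asarray(self.stationary, dtype=float)
        self.exchange = np.asarray(self.exchange, dtype=float)
        if self.emission_means is not None:
            self.emission_means = np.asarray(self.emission_means, dtype=float)
        self.validate()

    def validate(self) -> None:
        pi, P = self.stationary, self.exchange
        if pi.shape != (self.n_states,):
            raise ValidationError("stationary length must equal n_states")
        if np.any(pi <= 0):
            raise ValidationError("stationary entries must be > 0")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValidationError("stationary must sum to 1 within 1e-12")
        if P.shape != (self.n_states, self.n_states):
            raise ValidationError("exchange must be n_states x n_states")
        if np.any(P < 0):
            raise ValidationError("exchange entries must be >= 0 (stochastic matrix)")
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-12:
            raise ValidationError("exchange rows must sum to 1 within 1e-12 (row-stochastic)")
        flux = pi[:, None] * P
        if np.max(np.abs(flux - flux.T)) > 1e-10:
            raise ValidationError(
                "exchange must satisfy detailed balance with stationary within 1e-10")
        if self.n_traj < 1 or self.n_steps < 1:
            raise ValidationError("n_traj and n_steps must be >= 1")
        if self.emission_means is not None:
            if self.emission_means.ndim != 2 or self.emission_means.shape[0] != self.n_states:
                raise ValidationError(
                    "emission_means must have one row of equal length per state")
            sd = np.atleast_1d(np.asarray(self.emission_sd, dtype=float))
            if sd.size not in (1, self.emission_means.shape[1]):
                raise ValidationError(
                    "emission_sd must be scalar or one value per feature")

    @property
    def n_features(self) -> int:
        if self.emission_means is None:
            raise ValidationError("spec has no emission_means")
        return self.emission_means.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [f"f{i:02d}" for i in range(self.n_features)]


def metropolis_exchange(stationary, move_prob: float = 0.02) -> np.ndarray:
    """Reversible row-stochastic jump matrix with the given stationary law.

    Off-diagonal entries are Metropolis moves ``move_prob * min(1, pi_j/pi_i)``,
    which satisfy detailed balance by construction; the diagonal absorbs the
    remainder. ``move_prob`` sets the exchange timescale (smaller = slower).
    """
    pi = np.asarray(stationary, dtype=float)
    n = pi.size
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                P[i, j] = move_prob * min(1.0, pi[j] / pi[i])
        P[i, i] = 1.0 - P[i].sum()
        if P[i, i] < 0:
            raise ValidationError("move_prob too large for this stationary vector")
    return P


def _separated_means(n_states: int, n_features: int,
                     baseline: float = 8.0, separation: float = 2.0) -> np.ndarray:
    """State mean vectors that differ by `separation` on interleaved features."""
    means = np.full((n_states, n_features), baseline)
    for s in range(n_states):
        means[s, np.arange(n_features) % n_states == s] += separation
    return means


def default_system_spec(seed: int = 0, *, n_traj: int = 40, n_steps: int = 5000,
                        move_prob: float = 0.02) -> ToySystemSpec:
    """The desk-scale reference scenario used throughout the test suite.

    Three metastable states with stationary [0.50, 0.30, 0.20], 40
    trajectories x 5000 frames at 0.3 ns/frame, 16 Gaussian features with
    4-sigma state separation: a multi-trajectory design small enough to
    analyse in minutes but rich enough to recover populations and rates.
    """
    stationary = np.array([0.50, 0.30, 0.20])
    return ToySystemSpec(
        n_states=3,
        stationary=stationary,
        exchange=metropolis_exchange(stationary, move_prob),
        n_traj=n_traj,
        n_steps=n_steps,
        dt=0.3,
        emission_means=_separated_means(3, 16),
        emission_sd=0.5,
        seed=seed,
    )


def simulate_hidden_chain(spec: ToySystemSpec,
                          start_dist: np.ndarray | None = None) -> list[np.ndarray]:
    """Simulate per-trajectory hidden metastable-state index sequences.

    Initial states are drawn from the stationary distribution (or from
    ``start_dist``, e.g. to emulate a sampling campaign started from one
    basin), transitions from the exchange matrix; each trajectory uses its
    own seeded substream.
    """
    spec.validate()
    cum = np.cumsum(spec.exchange, axis=1)
    cum_pi = np.cumsum(spec.stationary if start_dist is None
                       else np.asarray(start_dist, dtype=float))
    out = []
    for k in range(spec.n_traj):
        rng = _substream(spec.seed, _CHAIN_STREAM, k)
        u = rng.random(spec.n_steps)
        states = np.empty(spec.n_steps, dtype=np.int64)
        s = int(np.searchsorted(cum_pi, u[0], side="right"))
        states[0] = min(s, spec.n_states - 1)
        for t in range(1, spec.n_steps):
            row = cum[states[t - 1]]
            states[t] = min(int(np.searchsorted(row, u[t], side="right")),
                            spec.n_states - 1)
        out.append(states)
    return out


def emit_features(states: list[np.ndarray], spec: ToySystemSpec) -> list[FeatureTrajectory]:
    """Gaussian feature emissions around each frame's hidden-state mean."""
    spec.validate()
    if spec.emission_means is None:
        raise ValidationError("spec has no emission_means")
    sd = np.broadcast_to(np.atleast_1d(np.asarray(spec.emission_sd, dtype=float)),
                         (spec.n_features,))
    trajs = []
    for k, seq in enumerate(states):
        seq = np.asarray(seq, dtype=int)
        if seq.size and seq.max() >= spec.n_states:
            raise ValidationError("hidden state index exceeds n_states")
        rng = _substream(spec.seed, _FEATURE_STREAM, k)
        values = spec.emission_means[seq] + rng.normal(0.0, 1.0, (seq.size, spec.n_features)) * sd
        trajs.append(FeatureTrajectory(values=values, feature_names=spec.feature_names,
                                       dt=spec.dt, trajectory_id=f"traj{k:03d}"))
    return trajs


# ---------------------------------------------------------------------------
# toy 3-D structures
# ---------------------------------------------------------------------------

@dataclass
class ToyStructureSpec:
    """Per-state 3-D templates over one shared atom table, plus jitter.

    ``templates`` has shape (n_states, n_atoms, 3); emitted frames are the
    hidden state's template plus isotropic Gaussian noise of ``jitter_sd`` A.
    """

    atoms: pd.DataFrame
    templates: np.ndarray
    jitter_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.ndim != 3 or self.templates.shape[2] != 3:
            raise ValidationError("templates must have shape (n_states, n_atoms, 3)")
        if self.templates.shape[1] != len(self.atoms):
            raise ValidationError("templates must share atom count and ordering "
                                  "with the atom table across states")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be >= 0")

    @property
    def n_states(self) -> int:
        return self.templates.shape[0]


_BACKBONE = ("N", "CA", "C", "O")


def _loop_template(n_res: int, rng: np.random.Generator, amplitude: float = 3.0) -> np.ndarray:
    """A smooth random open curve with 4 backbone pseudo-atoms per residue."""
    t = np.linspace(0.0, 1.0, n_res)
    phases = rng.uniform(0, 2 * np.pi, (3, 3))
    amps = rng.uniform(0.5, 1.0, (3, 3)) * amplitude
    ca = np.stack([sum(amps[d, h] * np.sin((h + 1) * np.pi * t + phases[d, h])
                       for h in range(3)) for d in range(3)], axis=1)
    ca[:, 0] += np.linspace(0, 3.8 * (n_res - 1), n_res)  # extended backbone spacing
    offsets = np.array([[-0.5, 0.9, 0.0], [0.0, 0.0, 0.0],
                        [0.8, -0.7, 0.4], [1.2, -1.5, 0.6]])
    return (ca[:, None, :] + offsets[None, :, :]).reshape(-1, 3)


def default_structure_spec(n_states: int = 3, *, n_loop_res: int = 12,
                           loop_rmsd: float = 12.0,
                           subsegment_centers: np.ndarray | None = None,
                           jitter_sd: float = 0.5, seed: int = 0) -> ToyStructureSpec:
    """Build the default toy structure: loop + 4 Cbeta helices + pseudo-ligand.

    Loop templates of successive states differ by ``loop_rmsd`` A after
    optimal superposition (designed, for clustering ground truth). Helical
    subsegments are rigid 6-residue Cbeta stacks around designed per-state
    centers; the pseudo-ligand carries atoms N1-N4, the amide O1 and
    5-/6-membered rings, shifted slightly between states.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))

    # --- flexible N-terminal pseudo-loop ------------------------------------
    base = _loop_template(n_loop_res, rng)
    loop_templates = [base]
    for s in range(1, n_states):
        raw = _loop_template(n_loop_res, rng)
        loop_templates.append(scale_template_rmsd(base, raw, loop_rmsd * s / max(1, n_states - 1)
                                                  if n_states > 2 else loop_rmsd))
    loop_atoms = pd.DataFrame({
        "segment": "loop",
        "residue_id": np.repeat(np.arange(1, n_loop_res + 1), len(_BACKBONE)),
        "atom_name": list(_BACKBONE) * n_loop_res,
        "element": [a[0] for a in _BACKBONE] * n_loop_res,
    })

    # --- four pseudo-helical subsegments (one Cbeta per residue) ------------
    if subsegment_centers is None:
        ring = np.array([[14.0, 0.0, -20.0], [0.0, 14.0, -20.0],
                         [-14.0, 0.0, -20.0], [0.0, -14.0, -20.0]])
        # states differ in pocket size: the helix ring breathes radially
        subsegment_centers = np.stack([
            ring * np.array([1.0 + 0.05 * s, 1.0 + 0.05 * s, 1.0])
            for s in range(n_states)])
    subsegment_centers = np.asarray(subsegment_centers, dtype=float)
    n_per_helix = 6
    helix_local = np.stack([np.array([1.5 * np.cos(2.0 * i), 1.5 * np.sin(2.0 * i),
                                      1.5 * (i - (n_per_helix - 1) / 2)])
                            for i in range(n_per_helix)])
    helix_atoms, helix_templates = [], []
    res_id = 100
    for h in range(4):
        for i in range(n_per_helix):
            helix_atoms.append({"segment": f"TM{h + 1}e", "residue_id": res_id,
                                "atom_name": "CB", "element": "C"})
            res_id += 1
    for s in range(n_states):
        coords = [subsegment_centers[s, h] + helix_local for h in range(4)]
        helix_templates.append(np.concatenate(coords, axis=0))
    helix_atoms = pd.DataFrame(helix_atoms)

    # --- pseudo-ligand ------------------------------------------------------
    lig_names = ["N1", "N2", "N3", "N4", "O1"]
    lig_elements = ["N", "N", "N", "N", "O"]
    lig_base = np.array([[10.0, 0.0, -21.0], [8.0, 1.0, -20.0], [6.0, 1.5, -19.5],
                         [4.5, 2.5, -19.0], [5.5, 3.5, -20.0]])
    ring5 = np.array([[3.0 + np.cos(2 * np.pi * i / 5), 3.0 + np.sin(2 * np.pi * i / 5), -19.0]
                      for i in range(5)])
    ring6 = np.array([[1.0 + 1.2 * np.cos(2 * np.pi * i / 6),
                       4.0 + 1.2 * np.sin(2 * np.pi * i / 6), -18.5] for i in range(6)])
    for i in range(5):
        lig_names.append(f"C5{chr(ord('A') + i)}")
        lig_elements.append("C")
    for i in range(6):
        lig_names.append(f"C6{chr(ord('A') + i)}")
        lig_elements.append("C")
    lig_template_base = np.concatenate([lig_base, ring5, ring6], axis=0)
    lig_atoms = pd.DataFrame({"segment": "ligand", "residue_id": 900,
                              "atom_name": lig_names, "element": lig_elements})
    lig_templates = [lig_template_base + np.array([0.8 * s, 0.5 * s, -0.4 * s])
                     for s in range(n_states)]

    atoms = pd.concat([loop_atoms, helix_atoms, lig_atoms], ignore_index=True)
    atoms["is_heavy"] = atoms["element"] != "H"
    templates = np.stack([np.concatenate([loop_templates[s], helix_templates[s],
                                          lig_templates[s]], axis=0)
                          for s in range(n_states)])
    return ToyStructureSpec(atoms=atoms, templates=templates,
                            jitter_sd=jitter_sd, seed=seed)


def scale_template_rmsd(reference: np.ndarray, other: np.ndarray,
                        target_rmsd: float) -> np.ndarray:
    """Rescale `other`'s deviation from `reference` (after superposition) to a
    designed RMSD, giving templates with exact pairwise ground truth."""
    from .loops import superpose  # local import to avoid a cycle

    reference = np.asarray(reference, float)
    current = np.asarray(other, float)
    # rescaling the deviation shifts the optimal alignment, so iterate
    for _ in range(200):
        aligned = superpose(current, reference)
        dev = aligned - reference
        rmsd = float(np.sqrt((dev ** 2).sum() / len(reference)))
        if rmsd == 0:
            raise ValidationError("templates are identical; cannot scale to a nonzero RMSD")
        if abs(rmsd - target_rmsd) < 1e-12:
            return aligned
        current = reference + dev * (target_rmsd / rmsd)
    return current


def emit_coordinates(states: list[np.ndarray], spec: ToyStructureSpec) -> ConformerEnsemble:
    """Emit jittered template coordinates for every frame of every trajectory."""
    frames, coords = [], []
    for k, seq in enumerate(states):
        seq = np.asarray(seq, dtype=int)
        if seq.size and seq.max() >= spec.n_states:
            raise ValidationError(
                f"no template defined for hidden state {int(seq.max())}")
        rng = _substream(spec.seed, _COORD_STREAM, k)
        noise = rng.normal(0.0, spec.jitter_sd, (seq.size, spec.templates.shape[1], 3)) \
            if spec.jitter_sd > 0 else 0.0
        coords.append(spec.templates[seq] + noise)
        frames.append(pd.DataFrame({"traj": k, "frame": np.arange(seq.size),
                                    "state": seq}))
    return ConformerEnsemble(coordinates=np.concatenate(coords, axis=0),
                             atoms=spec.atoms,
                             frames=pd.concat(frames, ignore_index=True))


def rare_intermediate_spec(seed: int = 0, n_traj: int = 10,
                           n_steps: int = 150) -> ToySystemSpec:
    """A 3-state linear chain 0-1-2 with a rare intermediate middle state.

    There is no direct 0<->2 exchange, so trajectories started in basin 0
    and kept short rarely cross to basin 2: a designed scenario in which the
    first sampling round under-samples the far basin and adaptive seeding
    must rescue the equilibrium estimate.
    """
    stationary = np.array([0.55, 0.10, 0.35])
    P = np.zeros((3, 3))
    P[0, 1] = 0.01
    P[1, 0] = stationary[0] * P[0, 1] / stationary[1]
    P[1, 2] = 0.004
    P[2, 1] = stationary[1] * P[1, 2] / stationary[2]
    for i in range(3):
        P[i, i] = 1.0 - P[i].sum()
    return ToySystemSpec(n_states=3, stationary=stationary, exchange=P,
                         n_traj=n_traj, n_steps=n_steps, dt=0.3,
                         emission_means=_separated_means(3, 8),
                         emission_sd=0.5, seed=seed)


def rare_intermediate_campaign(seed: int = 0, n_main: int = 8,
                               main_steps: int = 60, probe_steps: int = 12):
    """Initial biased data + simulator for the adaptive-seeding scenario.

    The first round mimics a typical campaign start: ``n_main`` trajectories
    launched from the dominant basin (state 0), plus one very short probe
    started in the far basin (state 2, as from a docked starting pose). The
    probe's few frames form single-frame / under-sampled microstates that
    are disconnected from the main active set, so the round-0 model gets the
    far basin's equilibrium probability badly wrong and only adaptive
    seeding from those microstates can repair it.

    Returns (spec, initial feature trajectories, simulator).
    """
    main = rare_intermediate_spec(seed, n_traj=n_main, n_steps=main_steps)
    hidden = simulate_hidden_chain(main, start_dist=np.array([1.0, 0.0, 0.0]))
    probe_spec = rare_intermediate_spec(seed + 1, n_traj=1, n_steps=probe_steps)
    probe = simulate_hidden_chain(probe_spec, start_dist=np.array([0.0, 0.0, 1.0]))
    hidden = hidden + probe
    spec = rare_intermediate_spec(seed, n_traj=n_main + 1, n_steps=main_steps)
    trajs = emit_features(hidden[:n_main], main)
    probe_traj = emit_features(probe, probe_spec)[0]
    probe_traj.trajectory_id = f"traj{n_main:03d}"
    trajs.append(probe_traj)
    return spec, trajs, SyntheticSimulator(spec, hidden)


def estimated_basin_probability(partition, dtrajs, hidden: dict[str, np.ndarray],
                                basin: int) -> float:
    """Estimated equilibrium probability of a ground-truth basin.

    Sums pi_MS over the metastable states whose filtered member frames have
    the given hidden basin as their majority label (0.0 if no metastable
    state covers the basin — e.g. when it is disconnected from the active
    set). A campaign diagnostic only possible with synthetic ground truth.
    """
    total = 0.0
    for m in range(partition.n_ms):
        fs = partition.frame_sets[m]
        if fs.size == 0:
            continue
        labels = np.array([hidden[dtrajs[t].trajectory_id][f] for t, f in fs])
        if np.bincount(labels).argmax() == basin:
            total += float(partition.pi_ms["value"][m])
    return total


def nonmarkov_lumped_spec(seed: int = 0, n_traj: int = 8,
                          n_steps: int = 2000) -> tuple[ToySystemSpec, np.ndarray]:
    """A hidden 3-state chain whose 2-state lumping is strongly non-Markovian.

    Hidden states 1 and 2 exit their lump at very different rates (fast via
    1, sticky in 2), so the lumped process {0} vs {1,2} has a non-exponential
    survival curve that a 1-step Markov model cannot predict — a designed
    counterexample the Chapman-Kolmogorov test must detect. Returns the
    hidden-chain spec and the lumping map (hidden state -> visible state).
    """
    pi = np.array([10.0, 1.0, 25.0])
    pi = pi / pi.sum()
    P = np.array([[0.95, 0.05, 0.0],
                  [0.5, 0.45, 0.05],
                  [0.0, 0.002, 0.998]])
    spec = ToySystemSpec(n_states=3, stationary=pi, exchange=P,
                         n_traj=n_traj, n_steps=n_steps, dt=1.0,
                         emission_means=np.eye(3), emission_sd=0.0, seed=seed)
    return spec, np.array([0, 1, 1])


def feature_recipe_fixture() -> tuple[ConformerEnsemble, "object"]:
    """One-frame fixture on which the standard feature recipe yields 16 features.

    Twelve candidate residues are placed so that exactly 12 Cbeta-nitrogen
    pairs fall within the 7.0 A selection cutoff (each residue close to
    exactly one nitrogen, all other pairs beyond the cutoff); together with
    the two intramolecular distances and the two ring projections this gives
    the canonical 16-dimensional binding-mode feature vector.
    """
    from .featurize import FeatureSpec

    rows, coords = [], []
    # ligand: four nitrogens far apart, amide O, and two rings
    nitro_pos = np.array([[0.0, 0.0, 0.0], [40.0, 0.0, 0.0],
                          [80.0, 0.0, 0.0], [120.0, 0.0, 0.0]])
    for i, p in enumerate(nitro_pos, start=1):
        rows.append({"segment": "ligand", "residue_id": 900,
                     "atom_name": f"N{i}", "element": "N"})
        coords.append(p)
    rows.append({"segment": "ligand", "residue_id": 900, "atom_name": "O1",
                 "element": "O"})
    coords.append([121.0, 1.5, 0.0])
    ring_names = {"ring5": 5, "ring6": 6}
    for r, (rname, n_mem) in enumerate(ring_names.items()):
        for i in range(n_mem):
            rows.append({"segment": "ligand", "residue_id": 900,
                         "atom_name": f"{rname}_{i}", "element": "C"})
            coords.append([118.0 + 2 * r + np.cos(2 * np.pi * i / n_mem),
                           4.0 + np.sin(2 * np.pi * i / n_mem), 1.0])
    # 12 residues, 3 per nitrogen, each at 5-6.9 A of its nitrogen only
    rid = 1
    for j, p in enumerate(nitro_pos):
        for d in (5.0, 6.0, 6.9):
            rows.append({"segment": "protein", "residue_id": rid,
                         "atom_name": "CB", "element": "C"})
            coords.append(p + np.array([0.0, d, 0.0]))
            rid += 1
    atoms = pd.DataFrame(rows)
    atoms["is_heavy"] = True
    ens = ConformerEnsemble(coordinates=np.asarray(coords, float)[None, :, :],
                            atoms=atoms,
                            frames=pd.DataFrame({"traj": [0], "frame": [0]}))
    spec = FeatureSpec(
        candidate_residues=list(range(1, 13)),
        ring_definitions={name: [f"{name}_{i}" for i in range(n)]
                          for name, n in ring_names.items()})
    return ens, spec


def chain_mfpt(exchange: np.ndarray, source, target, dt: float = 1.0,
               stationary: np.ndarray | None = None) -> float:
    """Exact mean first passage time (ns) of the generating chain, by the
    absorbing-chain linear solve; the ground truth the pipeline must recover."""
    from .msm import mfpt_from_matrix

    return mfpt_from_matrix(np.asarray(exchange, float), source, target,
                            dt=dt, stationary=stationary)


class SyntheticSimulator:
    """Simulator hook for the adaptive-seeding loop.

    Plays the role a real MD engine would: given seed frames it continues the
    hidden chain from each seed frame's hidden state and emits features. It
    keeps a registry of every trajectory's hidden states so seed frames can be
    resolved, and hands out fresh trajectory ids.
    """

    def __init__(self, spec: ToySystemSpec, initial_hidden: list[np.ndarray]):
        self.spec = spec
        self.hidden: dict[str, np.ndarray] = {
            f"traj{k:03d}": np.asarray(h, dtype=int) for k, h in enumerate(initial_hidden)}
        self._next_index = len(initial_hidden)

    def hidden_state_of(self, traj_id: str, frame: int) -> int:
        return int(self.hidden[traj_id][frame])

    def run(self, seed_frames, n_steps: int, seed: int) -> list[FeatureTrajectory]:
        """Continue one new trajectory per seed frame; returns their features."""
        cum = np.cumsum(self.spec.exchange, axis=1)
        new_trajs = []
        for j, entry in enumerate(seed_frames):
            rng = np.random.default_rng(np.random.SeedSequence(
                [int(seed), _CHAIN_STREAM, self._next_index]))
            s = self.hidden_state_of(entry.trajectory_id, entry.frame_index)
            states = np.empty(n_steps, dtype=np.int64)
            u = rng.random(n_steps)
            for t in range(n_steps):
                s = min(int(np.searchsorted(cum[s], u[t], side="right")),
                        self.spec.n_states - 1)
                states[t] = s
            tid = f"traj{self._next_index:03d}"
            self.hidden[tid] = states
            feat = emit_features([states], ToySystemSpec(
                n_states=self.spec.n_states, stationary=self.spec.stationary,
                exchange=self.spec.exchange, n_traj=1, n_steps=n_steps,
                dt=self.spec.dt, emission_means=self.spec.emission_means,
                emission_sd=self.spec.emission_sd,
                seed=int(np.random.SeedSequence([int(seed), 5, self._next_index])
                         .generate_state(1)[0] % (2 ** 31))))[0]
            feat.trajectory_id = tid
            new_trajs.append(feat)
            self._next_index += 1
        return new_trajs
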