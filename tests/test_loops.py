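"""RMSF filtering, superposed pairwise RMSD, Ward cut rule and reweighting."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from posekin import loops, synthetic
from posekin.exceptions import ValidationError
from posekin.types import ConformerEnsemble


def _loop_ensemble(coord_frames, n_res):
    atoms = pd.DataFrame({
        "segment": "loop",
        "residue_id": np.repeat(np.arange(1, n_res + 1), 4),
        "atom_name": ["N", "CA", "C", "O"] * n_res,
        "element": ["N", "C", "C", "O"] * n_res,
    })
    atoms["is_heavy"] = True
    coords = np.asarray(coord_frames, dtype=float)
    frames = pd.DataFrame({"traj": 0, "frame": np.arange(len(coords))})
    return ConformerEnsemble(coordinates=coords, atoms=atoms, frames=frames)


def _rigid_frames(n_frames, n_res, seed=0, jitter=0.0):
    rng = np.random.default_rng(seed)
    base = rng.normal(0, 5, (n_res * 4, 3))
    out = []
    for _ in range(n_frames):
        x = base.copy()
        if jitter:
            x = x + rng.normal(0, jitter, x.shape)
        out.append(x)
    return np.stack(out), base


class TestRMSFFilter:
    def test_rigid_ensemble_keeps_everything(self):
        coords, _ = _rigid_frames(10, 6, jitter=0.05)
        ens = _loop_ensemble(coords, 6)
        kept, history = loops.iterative_rmsf_filter(ens, range(1, 7))
        assert kept == list(range(1, 7))
        assert history == [[]]

    def test_single_floppy_residue_excluded(self):
        rng = np.random.default_rng(1)
        coords, base = _rigid_frames(40, 6, jitter=0.05)
        floppy = slice(2 * 4, 3 * 4)  # residue 3
        coords[:, floppy] += rng.normal(0, 8.0, (40, 1, 3))
        ens = _loop_ensemble(coords, 6)
        kept, history = loops.iterative_rmsf_filter(ens, range(1, 7))
        assert kept == [1, 2, 4, 5, 6]
        assert history[0] == [3]

    def test_too_few_residues_rejected(self):
        coords, _ = _rigid_frames(5, 3, jitter=12.0, seed=2)
        ens = _loop_ensemble(coords, 3)
        with pytest.raises(ValidationError, match="3 residues"):
            loops.iterative_rmsf_filter(ens, range(1, 4), rmsf_cutoff=0.5)


class TestPairwiseRMSD:
    def test_self_and_rigid_copy_are_zero(self):
        coords, base = _rigid_frames(1, 5)
        rot = Rotation.from_euler("xyz", [30, 60, 10], degrees=True).as_matrix()
        moved = base @ rot.T + np.array([5.0, -3.0, 2.0])
        ens = _loop_ensemble(np.stack([base, moved]), 5)
        D = loops.pairwise_rmsd_matrix(ens, range(1, 6))
        assert D[0, 0] == 0.0
        assert D[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_single_displaced_atom_closed_form(self):
        coords, base = _rigid_frames(1, 25)  # N = 100 backbone atoms
        moved = base.copy()
        moved[0] += np.array([0.0, 0.0, 3.0])
        ens = _loop_ensemble(np.stack([base, moved]), 25)
        D = loops.pairwise_rmsd_matrix(ens, range(1, 26))
        n = 100
        # translation-corrected closed form 3*sqrt(n-1)/n; the optimal
        # rotation can only shave a little more off
        expect = 3 * np.sqrt(n - 1) / n
        assert D[0, 1] == pytest.approx(expect, rel=0.02)
        assert D[0, 1] <= expect + 1e-9

    def test_symmetry_and_superposition_optimality(self):
        rng = np.random.default_rng(3)
        coords, _ = _rigid_frames(6, 5, jitter=1.0, seed=3)
        ens = _loop_ensemble(coords, 5)
        D = loops.pairwise_rmsd_matrix(ens, range(1, 6))
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        # superposed RMSD never exceeds the raw coordinate RMSD
        for i in range(6):
            for j in range(i + 1, 6):
                raw = np.sqrt(((coords[i] - coords[j]) ** 2).sum(axis=1).mean())
                assert D[i, j] <= raw + 1e-9


class TestWardCut:
    def test_two_well_separated_groups(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 0.3, 30), rng.normal(12, 0.3, 20)])
        D = np.abs(x[:, None] - x[None, :])
        labels = loops.ward_cluster_cut(D)
        assert labels.max() == 1
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1

    def test_identical_frames_single_cluster(self):
        D = np.zeros((10, 10))
        labels = loops.ward_cluster_cut(D)
        assert np.all(labels == 0)

    def test_small_outlier_cluster_tolerated(self):
        # 4% of frames form a wide (7 A) far-away cluster: the rule lets it
        # stand without forcing further splits
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 0.3, 58), rng.normal(12, 0.3, 38),
                            rng.uniform(37, 51, 4)])
        D = np.abs(x[:, None] - x[None, :])
        labels = loops.ward_cluster_cut(D, rmsd_limit=5.0, small_cluster_frac=0.05)
        outlier_label = labels[-1]
        assert np.all(labels[-4:] == outlier_label)
        members = np.flatnonzero(labels == outlier_label)
        assert len(members) == 4
        sub = D[np.ix_(members, members)]
        assert sub[np.triu_indices(4, 1)].mean() > 5.0  # wide but tolerated
        assert labels.max() + 1 == 3

    def test_labels_invariant_to_frame_order(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 0.4, 25), rng.normal(10, 0.4, 15)])
        D = np.abs(x[:, None] - x[None, :])
        labels = loops.ward_cluster_cut(D)
        perm = rng.permutation(40)
        labels_p = loops.ward_cluster_cut(D[np.ix_(perm, perm)])
        # same partition up to label names
        for c in range(labels_p.max() + 1):
            orig = labels[perm][labels_p == c]
            assert len(set(orig)) == 1


class TestReweighting:
    def test_single_ms_keeps_raw_percentages(self):
        labels = np.array([0] * 7 + [1] * 3)
        pops = loops.reweight_populations(labels, np.zeros(10, dtype=int), {0: 1.0})
        assert np.allclose(pops, [70.0, 30.0])

    def test_two_ms_analytic_reweighting(self):
        labels = np.array([0] * 5 + [1] * 5)
        ms = np.array([0] * 5 + [1] * 5)
        pops = loops.reweight_populations(labels, ms, {0: 0.8, 1: 0.2})
        assert np.allclose(pops, [80.0, 20.0])

    def test_matches_explicit_weighted_recount(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 3, 200)
        ms = rng.integers(0, 2, 200)
        pi = {0: 0.6, 1: 0.4}
        pops = loops.reweight_populations(labels, ms, pi)
        counts = {m: (ms == m).sum() for m in (0, 1)}
        expect = np.zeros(3)
        for lab, m in zip(labels, ms):
            expect[lab] += pi[m] / counts[m]
        expect = 100 * expect / expect.sum()
        assert np.allclose(pops, expect)

    def test_unknown_ms_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            loops.reweight_populations(np.zeros(3, int), np.array([0, 1, 0]),
                                       {0: 1.0})


class TestEndToEnd:
    def test_two_template_loops_recovered(self, two_state_loop_ensemble):
        sspec, ens = two_state_loop_ensemble
        residues = sorted(set(
            sspec.atoms.loc[sspec.atoms.segment == "loop", "residue_id"]))
        res = loops.cluster_loop_conformations(ens, residues, skip_rmsf_filter=True)
        truth = ens.frames["state"].to_numpy()
        agreement = max((res.labels == truth).mean(), (res.labels != truth).mean())
        assert res.labels.max() + 1 == 2
        assert agreement > 0.99

    def test_reweighting_to_even_equilibrium(self, two_state_loop_ensemble):
        # designed 70/30 frame mixture reweighted by pi_MS = 50/50
        sspec, ens = two_state_loop_ensemble
        residues = sorted(set(
            sspec.atoms.loc[sspec.atoms.segment == "loop", "residue_id"]))
        res = loops.cluster_loop_conformations(
            ens, residues, frame_ms=ens.frames["state"].to_numpy(),
            pi_ms={0: 0.5, 1: 0.5}, skip_rmsf_filter=True)
        assert np.allclose(np.sort(res.reweighted_populations), [50.0, 50.0],
                           atol=2.0)

    def test_representatives_are_medoid_plus_neighbours(self, two_state_loop_ensemble):
        sspec, ens = two_state_loop_ensemble
        residues = sorted(set(
            sspec.atoms.loc[sspec.atoms.segment == "loop", "residue_id"]))
        res = loops.cluster_loop_conformations(ens, residues, skip_rmsf_filter=True)
        for c, reps in res.representatives.items():
            assert len(reps) == 5
            assert np.all(res.labels[reps] == c)
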