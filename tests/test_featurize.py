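"""Geometric features and ensemble observables against brute-force oracles."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from posekin import featurize, synthetic
from posekin.exceptions import ValidationError
from posekin.featurize import FeatureSpec
from posekin.types import ConformerEnsemble, SubsegmentDef


def _ensemble(coords, atoms_rows, frames=None):
    atoms = pd.DataFrame(atoms_rows)
    if "is_heavy" not in atoms:
        atoms["is_heavy"] = atoms["element"] != "H"
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if frames is None:
        frames = pd.DataFrame({"traj": 0, "frame": np.arange(len(coords))})
    return ConformerEnsemble(coordinates=coords, atoms=atoms, frames=frames)


def _nitrogen_and_residue(cb_distance):
    atoms = [
        {"segment": "ligand", "residue_id": 900, "atom_name": "N1", "element": "N"},
        {"segment": "protein", "residue_id": 7, "atom_name": "CB", "element": "C"},
    ]
    coords = [[0.0, 0.0, 0.0], [cb_distance, 0.0, 0.0]]
    return _ensemble(coords, atoms)


class TestResidueSelection:
    def test_pair_inside_cutoff_included(self):
        ens = _nitrogen_and_residue(6.90)
        spec = FeatureSpec(ligand_nitrogens=["N1"], candidate_residues=[7])
        assert featurize.select_feature_residues(ens, spec) == [("N1", 7)]

    def test_pair_outside_cutoff_excluded(self):
        ens = _nitrogen_and_residue(7.10)
        spec = FeatureSpec(ligand_nitrogens=["N1"], candidate_residues=[7])
        assert featurize.select_feature_residues(ens, spec) == []

    def test_boundary_is_inclusive(self):
        ens = _nitrogen_and_residue(7.0)
        spec = FeatureSpec(ligand_nitrogens=["N1"], candidate_residues=[7])
        assert featurize.select_feature_residues(ens, spec) == [("N1", 7)]

    def test_missing_cbeta_names_the_residue(self):
        ens = _nitrogen_and_residue(5.0)
        spec = FeatureSpec(ligand_nitrogens=["N1"], candidate_residues=[7, 8])
        with pytest.raises(ValidationError, match="8"):
            featurize.select_feature_residues(ens, spec)

    def test_twelve_pairs_give_sixteen_features(self):
        ens, spec = synthetic.feature_recipe_fixture()
        pairs = featurize.select_feature_residues(ens, spec)
        assert len(pairs) == 12
        traj = featurize.compute_feature_matrix(ens, pairs, spec)
        assert traj.n_features == 16


class TestFeatureMatrix:
    def test_three_four_five_distance(self):
        atoms = [
            {"segment": "ligand", "residue_id": 900, "atom_name": "N1", "element": "N"},
            {"segment": "protein", "residue_id": 1, "atom_name": "CB", "element": "C"},
        ]
        ens = _ensemble([[0, 0, 0], [3, 0, 4]], atoms)
        spec = FeatureSpec(ligand_nitrogens=["N1"], intramolecular_pairs=[])
        traj = featurize.compute_feature_matrix(ens, [("N1", 1)], spec)
        assert traj.values[0, 0] == pytest.approx(5.0)

    def test_ring_projection_is_signed_dot_product(self):
        atoms = [{"segment": "ligand", "residue_id": 900, "atom_name": n, "element": "C"}
                 for n in ["R_0", "R_1", "R_2"]]
        atoms.append({"segment": "ligand", "residue_id": 900, "atom_name": "N4",
                      "element": "N"})
        # ring COM at origin, N4 at (1, 2, 2), membrane normal +z
        ens = _ensemble([[1, 0, 0], [-0.5, np.sqrt(3) / 2, 0],
                         [-0.5, -np.sqrt(3) / 2, 0], [1, 2, 2]], atoms)
        spec = FeatureSpec(ligand_nitrogens=["N4"], intramolecular_pairs=[],
                           ring_definitions={"ring": ["R_0", "R_1", "R_2"]})
        traj = featurize.compute_feature_matrix(ens, [], spec)
        assert traj.values[0, 0] == pytest.approx(2.0)

    def test_matches_explicit_per_frame_loops(self):
        ens, spec = synthetic.feature_recipe_fixture()
        rng = np.random.default_rng(4)
        coords = ens.coordinates + rng.normal(0, 0.3, (5,) + ens.coordinates.shape[1:])
        ens5 = ConformerEnsemble(coordinates=coords, atoms=ens.atoms,
                                 frames=pd.DataFrame({"traj": 0, "frame": range(5)}))
        pairs = featurize.select_feature_residues(ens, spec)
        traj = featurize.compute_feature_matrix(ens5, pairs, spec)
        # independent brute-force recomputation, explicit loops
        name_to_idx = {n: i for i, n in enumerate(ens.atoms["atom_name"])}
        for f in range(5):
            col = 0
            for nitro, rid in pairs:
                cb = ens.atoms.index[(ens.atoms["residue_id"] == rid)
                                     & (ens.atoms["atom_name"] == "CB")][0]
                expect = np.linalg.norm(coords[f, name_to_idx[nitro]] - coords[f, cb])
                assert traj.values[f, col] == pytest.approx(expect, abs=1e-10)
                col += 1
            for a, b in spec.intramolecular_pairs:
                expect = np.linalg.norm(coords[f, name_to_idx[a]] - coords[f, name_to_idx[b]])
                assert traj.values[f, col] == pytest.approx(expect, abs=1e-10)
                col += 1
            for ring, members in spec.ring_definitions.items():
                com = np.mean([coords[f, name_to_idx[m]] for m in members], axis=0)
                expect = (coords[f, name_to_idx["N4"]] - com) @ np.array([0, 0, 1.0])
                assert traj.values[f, col] == pytest.approx(expect, abs=1e-10)
                col += 1

    def test_distances_rotation_invariant_projections_axis_dependent(self):
        ens, spec = synthetic.feature_recipe_fixture()
        pairs = featurize.select_feature_residues(ens, spec)
        base = featurize.compute_feature_matrix(ens, pairs, spec).values
        # rotation about the membrane normal keeps everything
        rot_z = Rotation.from_euler("z", 73, degrees=True).as_matrix()
        ens_z = ConformerEnsemble(coordinates=ens.coordinates @ rot_z.T + 5.0,
                                  atoms=ens.atoms, frames=ens.frames)
        assert np.allclose(featurize.compute_feature_matrix(ens_z, pairs, spec).values,
                           base, atol=1e-9)
        # a general rotation keeps distances but changes the projections
        rot = Rotation.from_euler("xyz", [40, 25, 10], degrees=True).as_matrix()
        ens_r = ConformerEnsemble(coordinates=ens.coordinates @ rot.T,
                                  atoms=ens.atoms, frames=ens.frames)
        rotated = featurize.compute_feature_matrix(ens_r, pairs, spec).values
        assert np.allclose(rotated[:, :14], base[:, :14], atol=1e-9)
        assert not np.allclose(rotated[:, 14:], base[:, 14:], atol=1e-3)


class TestMinGroupDistance:
    def test_singletons_and_min_selection(self):
        frame = np.array([[0, 0, 0], [2.7, 0, 0], [3.1, 0, 0], [0, 2.5, 0]])
        assert featurize.min_group_distance(frame, [0], [1]) == pytest.approx(2.7)
        assert featurize.min_group_distance(frame, [0], [2, 3]) == pytest.approx(2.5)
        with pytest.raises(ValidationError):
            featurize.min_group_distance(frame, [], [1])

    def test_matches_exhaustive_double_loop(self):
        rng = np.random.default_rng(1)
        frame = rng.normal(0, 5, (20, 3))
        ga, gb = np.arange(10), np.arange(10, 20)
        expect = min(np.linalg.norm(frame[i] - frame[j]) for i in ga for j in gb)
        assert featurize.min_group_distance(frame, ga, gb) == pytest.approx(expect)


def _contact_ensemble(n_frames, n_close):
    """Ligand atom at origin; residue 1 within 4 A in the first n_close frames."""
    atoms = [
        {"segment": "ligand", "residue_id": 900, "atom_name": "C1", "element": "C"},
        {"segment": "protein", "residue_id": 1, "atom_name": "CB", "element": "C"},
    ]
    coords = np.zeros((n_frames, 2, 3))
    coords[:, 1, 0] = 10.0
    coords[:n_close, 1, 0] = 4.0
    return _ensemble(coords, atoms)


class TestContactFrequencies:
    def test_always_in_contact(self):
        ens = _contact_ensemble(10, 10)
        tab = featurize.contact_frequencies(ens, [0], [1])
        assert tab["mean"].iloc[0] == pytest.approx(1.0)
        assert tab["sd"].iloc[0] == 0.0

    def test_half_contact(self):
        ens = _contact_ensemble(10, 5)
        tab = featurize.contact_frequencies(ens, [0], [1])
        assert tab["mean"].iloc[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("freq,display", [(0.66, True), (0.64, False)])
    def test_display_threshold(self, freq, display):
        ens = _contact_ensemble(100, int(100 * freq))
        tab = featurize.contact_frequencies(ens, [0], [1])
        assert bool(tab["display"].iloc[0]) is display
        assert bool(tab["listed"].iloc[0]) is True

    def test_infinite_cutoff_gives_unit_frequency(self):
        ens = _contact_ensemble(10, 0)
        tab = featurize.contact_frequencies(ens, [0], [1], cutoff=np.inf)
        assert tab["mean"].iloc[0] == pytest.approx(1.0)

    def test_zero_weights_rejected(self):
        ens = _contact_ensemble(4, 2)
        ens.frames["weight"] = 0.0
        with pytest.raises(ValidationError, match="zero"):
            featurize.contact_frequencies(ens, [0], [1])


class TestHbondFrequency:
    def _hbond_ensemble(self, da_dist, angle_deg):
        # donor heavy at origin, H on the x axis, acceptor placed to give the
        # requested donor-H...acceptor angle
        atoms = [
            {"segment": "protein", "residue_id": 1, "atom_name": "OG", "element": "O"},
            {"segment": "protein", "residue_id": 1, "atom_name": "HG", "element": "H"},
            {"segment": "protein", "residue_id": 2, "atom_name": "OE1", "element": "O"},
        ]
        h = np.array([1.0, 0.0, 0.0])
        theta = np.radians(180.0 - angle_deg)
        acc = h + (da_dist - 1.0) * np.array([np.cos(theta), np.sin(theta), 0.0])
        acc = acc / np.linalg.norm(acc - h) * 0 + acc  # keep geometry explicit
        # rescale so donor-acceptor distance equals da_dist
        acc = acc * (da_dist / np.linalg.norm(acc))
        return _ensemble([[0, 0, 0], h, acc], atoms)

    def test_close_linear_geometry_counts(self):
        ens = self._hbond_ensemble(2.8, 170.0)
        assert featurize.hbond_frequency(ens, (0, 1), [2]) == pytest.approx(1.0)

    def test_long_distance_does_not_count(self):
        ens = self._hbond_ensemble(4.5, 170.0)
        assert featurize.hbond_frequency(ens, (0, 1), [2]) == 0.0

    def test_unknown_criterion_rejected(self):
        ens = self._hbond_ensemble(2.8, 170.0)
        with pytest.raises(ValidationError, match="criterion"):
            featurize.hbond_frequency(ens, (0, 1), [2], criterion="nope")

    def test_constructed_30_percent_frequency(self):
        rng = np.random.default_rng(7)
        n = 400
        atoms = [
            {"segment": "a", "residue_id": 1, "atom_name": "O1", "element": "O"},
            {"segment": "b", "residue_id": 2, "atom_name": "O2", "element": "O"},
        ]
        coords = np.zeros((n, 2, 3))
        within = rng.random(n) < 0.30
        coords[:, 1, 0] = np.where(within, 3.0, 6.0)
        ens = _ensemble(coords, atoms)
        freq = featurize.hbond_frequency(ens, [0], [1], criterion="distance_only")
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(freq - within.mean()) < 1e-12
        assert abs(freq - 0.30) < 3 * se


class TestSubsegmentDistance:
    def test_single_atom_subsegments(self):
        atoms = [
            {"segment": "p", "residue_id": 1, "atom_name": "CB", "element": "C"},
            {"segment": "p", "residue_id": 2, "atom_name": "CB", "element": "C"},
        ]
        ens = _ensemble([[0, 0, 0], [8, 0, 0]], atoms)
        d = featurize.subsegment_com_distance(
            ens.coordinates[0], ens.atoms,
            (SubsegmentDef("A", [1]), SubsegmentDef("B", [2])))
        assert d == pytest.approx(8.0)

    def test_symmetric_two_atom_groups(self):
        atoms = [{"segment": "p", "residue_id": r, "atom_name": "CB", "element": "C"}
                 for r in (1, 1, 2, 2)]
        coords = [[-5, 1, 0], [-5, -1, 0], [5, 1, 0], [5, -1, 0]]
        ens = _ensemble(coords, atoms)
        d = featurize.subsegment_com_distance(
            ens.coordinates[0], ens.atoms,
            (SubsegmentDef("A", [1]), SubsegmentDef("B", [2])))
        assert d == pytest.approx(10.0)

    def test_toy_helices_recover_designed_separation(self):
        centers = np.zeros((1, 4, 3))
        centers[0, 1] = [10.0, 0.0, 0.0]
        sspec = synthetic.default_structure_spec(
            n_states=1, subsegment_centers=centers, jitter_sd=0.2, seed=9)
        ens = synthetic.emit_coordinates([np.zeros(50, dtype=int)], sspec)
        tm1 = sorted(set(sspec.atoms.loc[sspec.atoms.segment == "TM1e", "residue_id"]))
        tm2 = sorted(set(sspec.atoms.loc[sspec.atoms.segment == "TM2e", "residue_id"]))
        dists = [featurize.subsegment_com_distance(
            ens.coordinates[f], ens.atoms,
            (SubsegmentDef("TM1e", tm1), SubsegmentDef("TM2e", tm2)))
            for f in range(ens.n_frames)]
        tol = 3 * 0.2 / np.sqrt(6)  # COM noise propagation, 6 atoms per helix
        assert abs(np.mean(dists) - 10.0) < tol

    def test_empty_range_rejected(self):
        with pytest.raises(ValidationError):
            SubsegmentDef("empty", [])
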