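import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from ktnkit.rna_descriptors import (
    annotate_base_pairs,
    base_frame,
    compute_descriptors,
    fit_pca,
    interhelical_angles,
    load_model,
    project,
    pucker_phase,
    sasa,
    sugar_torsions,
    wc_edge_distance,
    _rna_residues,
)
from ktnkit.synthetic_data import build_helix_fixture

from conftest import DUPLEX_PAIRS, DUPLEX_SEQ, make_atom_structure


def _transform_structure(structure, R=None, t=None, mirror_x=False):
    import copy

    out = copy.deepcopy(structure)
    for atom in out.get_atoms():
        c = np.asarray(atom.get_coord(), dtype=float)
        if mirror_x:
            c = c * np.array([-1.0, 1.0, 1.0])
        if R is not None:
            c = R @ c
        if t is not None:
            c = c + t
        atom.set_coord(c.astype(np.float32))
    return out


class TestBaseFrame:
    def test_frame_normal_aligns_with_ring_plane(self, duplex):
        structure, _ = duplex
        res = _rna_residues(load_model(structure))[1]
        origin, axes = base_frame(res)
        ring = np.array([res[a].get_coord() for a in ("N1", "C2", "N3",
                                                      "C4", "C5", "C6")])
        # all ring atoms lie in the plane orthogonal to z
        assert np.max(np.abs((ring - origin) @ axes[2])) < 1e-5
        np.testing.assert_allclose(axes @ axes.T, np.eye(3), atol=1e-10)

    def test_equivariance_under_rigid_motion(self, duplex):
        structure, _ = duplex
        R = Rotation.from_euler("xyz", [20, -35, 110], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 12.0])
        moved = _transform_structure(structure, R=R, t=t)
        o1, a1 = base_frame(_rna_residues(load_model(structure))[3])
        o2, a2 = base_frame(_rna_residues(load_model(moved))[3])
        np.testing.assert_allclose(o2, R @ o1 + t, atol=1e-4)
        np.testing.assert_allclose(a2, a1 @ R.T, atol=1e-4)

    def test_missing_ring_atoms_named(self):
        structure = make_atom_structure([(1, "C2", "C", [0, 0, 0])])
        structure[0]["A"].child_list[0].resname = "  G"
        res = next(load_model(structure).get_residues())
        with pytest.raises(KeyError, match="ring"):
            base_frame(res)


class TestAnnotation:
    def test_duplex_yields_exactly_constructed_cww_pairs(self, duplex):
        structure, truth = duplex
        found = annotate_base_pairs(structure)
        assert [(p.i, p.j, p.category) for p in found] == \
            [(t.i, t.j, "cWW") for t in truth]

    def test_invariant_under_global_rotation_translation(self, duplex):
        structure, _ = duplex
        R = Rotation.from_euler("zxz", [75, 40, -10], degrees=True).as_matrix()
        moved = _transform_structure(structure, R=R, t=np.array([-8.0, 2.0, 30.0]))
        assert [(p.i, p.j, p.category) for p in annotate_base_pairs(moved)] == \
            [(p.i, p.j, p.category) for p in annotate_base_pairs(structure)]

    def test_single_nucleotide_has_no_pairs(self):
        structure, _ = build_helix_fixture("G", [])
        assert annotate_base_pairs(structure) == []

    def test_sliding_one_base_down_the_axis_breaks_only_that_pair(self, duplex):
        structure, truth = duplex
        import copy

        moved = copy.deepcopy(structure)
        chain = next(load_model(moved).get_chains())
        res12 = [r for r in chain if r.id[1] == 12][0]
        for atom in res12:
            atom.set_coord(np.asarray(atom.get_coord()) + np.array([0, 0, 3.0]))
        found = {(p.i, p.j): p.category for p in annotate_base_pairs(moved)}
        assert found.get((1, 12), "absent") in ("absent", "XXX")
        for t in truth:
            if (t.i, t.j) != (1, 12):
                assert found[(t.i, t.j)] == "cWW"

    def test_bulge_fixture_pairs_only_the_stems(self):
        # hairpin-like: 4 paired, 2 flipped-out bulge residues
        seq = "GGGGAACCCC"
        pairing = [(1, 10), (2, 9), (3, 8), (4, 7)]
        structure, truth = build_helix_fixture(seq, pairing)
        found = {(p.i, p.j) for p in annotate_base_pairs(structure)}
        assert found == {(t.i, t.j) for t in truth}


class TestWCDistance:
    def test_paired_bases_sit_near_three_angstroms(self, duplex):
        structure, truth = duplex
        for t in truth:
            assert wc_edge_distance(structure, t.i, t.j) == \
                pytest.approx(2.9, abs=0.2)

    def test_same_residue_twice_is_zero(self, duplex):
        structure, _ = duplex
        assert wc_edge_distance(structure, 4, 4) == 0.0

    def test_atoms_placed_at_known_distance(self):
        structure, _ = build_helix_fixture("GC", [(1, 2)])
        model = load_model(structure)
        res = _rna_residues(model)
        d = np.linalg.norm(
            np.asarray(res[1]["N1"].get_coord(), dtype=float)
            - np.asarray(res[2]["N3"].get_coord(), dtype=float)
        )
        assert wc_edge_distance(structure, 1, 2) == pytest.approx(d, abs=1e-6)

    def test_missing_residue_raises(self, duplex):
        structure, _ = duplex
        with pytest.raises(KeyError):
            wc_edge_distance(structure, 1, 99)


class TestPucker:
    def test_matches_independent_torsion_oracle(self, duplex):
        """Recompute P from Bio.PDB dihedrals and the closed formula."""
        from Bio.PDB.vectors import calc_dihedral

        structure, _ = duplex
        res = _rna_residues(load_model(structure))[2]
        quads = [("C4'", "O4'", "C1'", "C2'"), ("O4'", "C1'", "C2'", "C3'"),
                 ("C1'", "C2'", "C3'", "C4'"), ("C2'", "C3'", "C4'", "O4'"),
                 ("C3'", "C4'", "O4'", "C1'")]
        nu = [math.degrees(calc_dihedral(*(res[a].get_vector() for a in q)))
              for q in quads]
        num = (nu[4] + nu[1]) - (nu[3] + nu[0])
        den = 2 * nu[2] * (math.sin(math.radians(36)) + math.sin(math.radians(72)))
        expected = math.degrees(math.atan2(num, den)) % 360.0
        assert pucker_phase(res) == pytest.approx(expected, abs=1e-3)

    def test_mirror_image_shifts_phase_by_half_turn(self, duplex):
        """Reflection negates every endocyclic torsion, so P -> P + 180.

        (The pucker amplitude is unchanged: the mirror of C3'-endo is
        C3'-exo, half a pseudorotation cycle away.)
        """
        structure, _ = duplex
        mirrored = _transform_structure(structure, mirror_x=True)
        p = pucker_phase(_rna_residues(load_model(structure))[3])
        pm = pucker_phase(_rna_residues(load_model(mirrored))[3])
        assert pm == pytest.approx((p + 180.0) % 360.0, abs=1e-3)

    def test_planar_ring_rejected(self, duplex):
        import copy

        structure, _ = duplex
        flat = copy.deepcopy(structure)
        res = _rna_residues(load_model(flat))[1]
        _, axes = base_frame(res)
        for name in ("C1'", "C2'", "C3'", "C4'", "O4'"):
            c = np.asarray(res[name].get_coord(), dtype=float)
            res[name].set_coord((c - (c @ axes[1]) * axes[1]).astype(np.float32))
        # project the sugar into a common plane -> amplitude ~ 0
        with pytest.raises(ValueError, match="planar"):
            pucker_phase(res)

    def test_torsions_sum_near_zero(self, duplex):
        structure, _ = duplex
        nu = sugar_torsions(_rna_residues(load_model(structure))[5])
        assert abs(nu.sum()) < 25.0  # closure constraint of a 5-ring


class TestInterhelical:
    def test_coaxial_stems_have_no_bend(self, duplex):
        structure, _ = duplex
        a, b, g = interhelical_angles(structure, DUPLEX_PAIRS[:3], DUPLEX_PAIRS[3:])
        assert abs(b) < 2.0

    @pytest.mark.parametrize("bend", [15.0, 30.0, 60.0, 90.0])
    def test_constructed_bend_recovered(self, bend):
        seq = "GGGGGGGGCCCCCCCC"
        pairing = [(i, 17 - i) for i in range(1, 9)]
        structure, _ = build_helix_fixture(seq, pairing, bend_angle=bend,
                                           bend_after_pair=4)
        _, beta, _ = interhelical_angles(structure, pairing[:4], pairing[4:])
        assert beta == pytest.approx(bend, abs=2.0)

    def test_rotated_copy_of_stem_frame_gives_90_degrees(self, duplex):
        structure, _ = duplex
        R = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        rotated = _transform_structure(structure, R=R)
        # compare stem 1 of the original against stem 1 of the rotated copy
        from ktnkit.rna_descriptors import _stem_frame

        res1 = _rna_residues(load_model(structure))
        res2 = _rna_residues(load_model(rotated))
        f1 = _stem_frame(res1, DUPLEX_PAIRS[:3])
        f2 = _stem_frame(res2, DUPLEX_PAIRS[:3])
        rel = f2.T @ f1
        _, beta, _ = Rotation.from_matrix(rel).as_euler("ZYZ", degrees=True)
        assert abs(beta) == pytest.approx(90.0, abs=1e-3)

    def test_too_few_pairs_rejected(self, duplex):
        structure, _ = duplex
        with pytest.raises(ValueError, match="3"):
            interhelical_angles(structure, DUPLEX_PAIRS[:2], DUPLEX_PAIRS[3:])


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        structure = make_atom_structure([(1, "C", "C", [0.0, 0.0, 0.0])])
        r = 1.7  # biopython carbon radius
        expect = 4 * math.pi * (r + 1.4) ** 2
        assert sasa(structure, 1) == pytest.approx(expect, rel=0.01)

    def test_distant_atoms_are_additive(self):
        structure = make_atom_structure([
            (1, "C", "C", [0.0, 0.0, 0.0]),
            (1, "C2", "C", [100.0, 0.0, 0.0]),
        ])
        single = make_atom_structure([(1, "C", "C", [0.0, 0.0, 0.0])])
        assert sasa(structure, 1) == pytest.approx(2 * sasa(single, 1), rel=1e-6)

    def test_fully_enclosed_atom_has_zero_area(self):
        shell = []
        golden = math.pi * (3 - math.sqrt(5))
        for k in range(40):
            z = 1 - 2 * (k + 0.5) / 40
            r = math.sqrt(1 - z * z)
            th = golden * k
            shell.append((2, f"S{k}", "C",
                          [3.0 * r * math.cos(th), 3.0 * r * math.sin(th), 3.0 * z]))
        structure = make_atom_structure([(1, "C", "C", [0.0, 0.0, 0.0])] + shell)
        assert sasa(structure, 1, radii={"C": 2.0}) == 0.0

    def test_custom_radius_scales_area(self):
        structure = make_atom_structure([(1, "C", "C", [0.0, 0.0, 0.0])])
        got = sasa(structure, 1, radii={"C": 2.0})
        assert got == pytest.approx(4 * math.pi * (2.0 + 1.4) ** 2, rel=0.01)


class TestDescriptorsAndPCA:
    def _ensemble(self, n=6):
        models = {}
        seq = "GGGGGGGGCCCCCCCC"
        pairing = [(i, 17 - i) for i in range(1, 9)]
        for k in range(n):
            structure, _ = build_helix_fixture(seq, pairing,
                                               bend_angle=10.0 * k,
                                               bend_after_pair=4)
            models[k + 1] = structure
        return models, pairing

    def test_descriptor_matrix_complete_for_generated_fixtures(self):
        models, pairing = self._ensemble(4)
        df = compute_descriptors(
            models,
            pair_distances=[(1, 16), (2, 15), (8, 9)],
            pucker_residues=(4, 5),
            stem1_pairs=pairing[:4], stem2_pairs=pairing[4:],
            sasa_residue=8,
        )
        assert list(df.columns) == ["d_1_16", "d_2_15", "d_8_9", "pucker_4",
                                    "pucker_5", "alpha", "beta", "gamma",
                                    "sasa_8"]
        assert not df.isna().any().any()
        assert (df.index == [1, 2, 3, 4]).all()

    def test_points_on_a_line_have_single_component(self):
        X = pd.DataFrame({"a": np.arange(10.0), "b": 3 * np.arange(10.0) + 1})
        model, scores = fit_pca(X)
        assert model.explained_var_ratio[0] == pytest.approx(1.0, abs=1e-12)
        assert model.explained_var_ratio[1] == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_gaussian_spreads_variance_evenly(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((10_000, 4)),
                         columns=list("abcd"))
        model, _ = fit_pca(X)
        # each ratio ~ 0.25 within sampling error (~ sqrt(2/n))
        np.testing.assert_allclose(model.explained_var_ratio, 0.25, atol=0.05)

    def test_projection_of_training_rows_reproduces_scores(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        model, scores = fit_pca(X)
        np.testing.assert_allclose(project(model, X), scores, atol=1e-10)

    def test_scores_invariant_under_feature_rescaling(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        model1, s1 = fit_pca(X)
        X2 = X * np.array([10.0, 0.01, 3.0]) + np.array([5.0, -2.0, 0.0])
        model2, s2 = fit_pca(X2)
        # components may flip sign; compare absolute scores
        np.testing.assert_allclose(np.abs(s1), np.abs(s2), atol=1e-8)

    def test_zero_variance_column_dropped_with_warning(self):
        X = pd.DataFrame({"a": np.arange(8.0), "b": np.ones(8)})
        with pytest.warns(UserWarning, match="zero-variance"):
            model, _ = fit_pca(X)
        assert model.feature_names == ["a"] and model.dropped == ["b"]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(pd.DataFrame({"a": [1.0]}))

    def test_loadings_orthonormal_and_ratios_descending(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 4)) * [3, 2, 1, 0.5],
                         columns=list("abcd"))
        model, _ = fit_pca(X)
        np.testing.assert_allclose(model.loadings @ model.loadings.T,
                                   np.eye(4), atol=1e-10)
        assert (np.diff(model.explained_var_ratio) <= 1e-12).all()
        assert model.explained_var_ratio.sum() <= 1 + 1e-9
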