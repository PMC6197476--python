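"""Coordinate primitives against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist

import absaxs as ax
from absaxs.errors import ValidationError
from absaxs.geometry import rotation_about_axis


def _points(xyz, chain="A"):
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    n = len(xyz)
    return ax.Structure(
        serial=np.arange(1, n + 1),
        chain_id=np.full(n, chain),
        res_id=np.arange(1, n + 1),
        res_name=np.full(n, "ALA"),
        atom_name=np.full(n, "CA"),
        element=np.full(n, "C"),
        coord=xyz,
    )


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert ax.radius_of_gyration(_points([[1, 2, 3]])) == 0.0

    def test_two_atoms_ten_apart(self):
        s = _points([[0, 0, 0], [10, 0, 0]])
        assert ax.radius_of_gyration(s) == pytest.approx(5.0)

    def test_uniform_ball_matches_closed_form(self):
        # Rg of a uniform ball of radius R is R sqrt(3/5)
        rng = np.random.default_rng(5)
        n, radius = 100_000, 30.0
        xyz = rng.normal(size=(n, 3))
        xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
        xyz *= radius * rng.uniform(size=(n, 1)) ** (1 / 3)
        expected = radius * np.sqrt(3.0 / 5.0)
        assert ax.radius_of_gyration(_points(xyz)) == pytest.approx(
            expected, rel=5e-3
        )

    def test_weighted(self):
        s = _points([[0, 0, 0], [10, 0, 0]])
        # all weight on one atom -> Rg 0
        assert ax.radius_of_gyration(s, weights=[1e9, 1e-9]) == pytest.approx(
            0.0, abs=1e-3
        )

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            ax.radius_of_gyration(_points(np.empty((0, 3))))


class TestSuperpose:
    def test_self_alignment_is_identity(self, fab):
        sel = (np.arange(fab.n_atoms), np.arange(fab.n_atoms))
        T, rmsd = ax.superpose(fab, fab, sel)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T.translation, 0.0, atol=1e-9)

    def test_recovers_known_transform(self, fab):
        rng = np.random.default_rng(3)
        R = Rotation.random(random_state=7).as_matrix()
        t = rng.uniform(-50, 50, 3)
        moved = fab.with_coord(fab.coord @ R.T + t)
        sel = (np.arange(fab.n_atoms), np.arange(fab.n_atoms))
        T, rmsd = ax.superpose(moved, fab, sel)
        assert rmsd < 1e-8
        # recovered transform must invert the applied one
        comp = T.compose(ax.Transform(R, t))
        np.testing.assert_allclose(comp.rotation, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(comp.translation, 0.0, atol=1e-6)

    def test_matches_independent_svd_oracle(self, fab):
        rng = np.random.default_rng(11)
        R = Rotation.random(random_state=13).as_matrix()
        ref = fab.with_coord(fab.coord @ R.T + rng.normal(0, 0.1, fab.coord.shape))
        sel = (np.arange(fab.n_atoms), np.arange(fab.n_atoms))
        T, rmsd = ax.superpose(fab, ref, sel)
        # oracle: scipy weighted Kabsch on centred clouds
        a = fab.coord - fab.coord.mean(0)
        b = ref.coord - ref.coord.mean(0)
        rot, _ = Rotation.align_vectors(b, a)
        oracle_rmsd = np.sqrt(((rot.apply(a) - b) ** 2).sum(1).mean())
        assert rmsd == pytest.approx(oracle_rmsd, abs=1e-9)

    def test_pre_rotation_invariance(self, fab):
        # RMSD must not change if the mobile structure is pre-rotated
        rng = np.random.default_rng(4)
        ref = fab.with_coord(fab.coord + rng.normal(0, 0.2, fab.coord.shape))
        sel = (np.arange(fab.n_atoms), np.arange(fab.n_atoms))
        _, rmsd1 = ax.superpose(fab, ref, sel)
        pre = Rotation.random(random_state=21).as_matrix()
        _, rmsd2 = ax.superpose(fab.with_coord(fab.coord @ pre.T), ref, sel)
        assert rmsd1 == pytest.approx(rmsd2, abs=1e-9)

    def test_degenerate_selection_errors(self):
        line = _points([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        sel = (np.arange(4), np.arange(4))
        with pytest.raises(ValidationError):
            ax.superpose(line, line, sel)


class TestMinPairDistance:
    @pytest.mark.parametrize(
        "d, rejected", [(7.99, True), (8.0, False), (8.01, False)]
    )
    def test_clash_rule_boundary(self, d, rejected, filters):
        # the 8 A rule is a strict inequality: exactly 8.0 A passes
        a = _points([[0, 0, 0]])
        b = _points([[d, 0, 0]], chain="B")
        md = ax.min_pair_distance(a, b)
        assert md == pytest.approx(d)
        assert (md < filters.clash_min) is rejected

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        a = _points(rng.uniform(-50, 50, (500, 3)))
        b = _points(rng.uniform(-30, 70, (500, 3)), chain="B")
        brute = cdist(a.coord, b.coord).min()
        assert ax.min_pair_distance(a, b) == brute

    def test_symmetric(self, fab, antigen):
        assert ax.min_pair_distance(fab, antigen) == pytest.approx(
            ax.min_pair_distance(antigen, fab)
        )


class TestThreePointAngle:
    def test_collinear_and_orthogonal(self):
        assert ax.three_point_angle([-1, 0, 0], [0, 0, 0], [2, 0, 0]) == pytest.approx(180.0)
        assert ax.three_point_angle([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_matches_arccos_oracle(self, antibody):
        c1 = antibody.centroid(antibody.label_indices("Fab1"))
        cf = antibody.centroid(antibody.label_indices("Fc"))
        c2 = antibody.centroid(antibody.label_indices("Fab2"))
        v1, v2 = c1 - cf, c2 - cf
        oracle = np.degrees(
            np.arccos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        )
        assert ax.three_point_angle(c1, cf, c2) == pytest.approx(oracle, abs=1e-9)

    def test_coincident_errors(self):
        with pytest.raises(ValidationError):
            ax.three_point_angle([0, 0, 0], [0, 0, 0], [1, 1, 1])


class TestApplyTorsion:
    def test_zero_delta_is_identity(self, antibody):
        out = ax.apply_torsion(antibody, ("A", 2, "phi"), 0.0)
        np.testing.assert_array_equal(out.coord, antibody.coord)

    def test_full_turn_is_identity(self, antibody):
        out = ax.apply_torsion(antibody, ("A", 2, "psi"), 360.0)
        np.testing.assert_allclose(out.coord, antibody.coord, atol=1e-9)

    def test_measured_dihedral_changes_by_delta(self, antibody):
        def backbone(s, res, name):
            m = (s.chain_id == "A") & (s.res_id == res) & (s.atom_name == name)
            return s.coord[np.flatnonzero(m)[0]]

        before = ax.measure_dihedral(
            backbone(antibody, 1, "C"),
            backbone(antibody, 2, "N"),
            backbone(antibody, 2, "CA"),
            backbone(antibody, 2, "C"),
        )
        out = ax.apply_torsion(antibody, ("A", 2, "phi"), 30.0)
        after = ax.measure_dihedral(
            backbone(out, 1, "C"),
            backbone(out, 2, "N"),
            backbone(out, 2, "CA"),
            backbone(out, 2, "C"),
        )
        assert (after - before + 180) % 360 - 180 == pytest.approx(30.0, abs=1e-9)

    def test_downstream_matches_rodrigues_oracle(self, antibody):
        delta = 30.0
        out = ax.apply_torsion(antibody, ("A", 2, "phi"), delta)
        sel_n = (antibody.chain_id == "A") & (antibody.res_id == 2) & (
            antibody.atom_name == "N"
        )
        sel_ca = (antibody.chain_id == "A") & (antibody.res_id == 2) & (
            antibody.atom_name == "CA"
        )
        pa = antibody.coord[np.flatnonzero(sel_n)[0]]
        pb = antibody.coord[np.flatnonzero(sel_ca)[0]]
        # independent axis-angle rotation of the downstream set
        T = rotation_about_axis(pa, pb - pa, -delta)
        movers = (antibody.chain_id == "A") & (
            (antibody.res_id > 2)
            | ((antibody.res_id == 2) & (antibody.atom_name == "C"))
        )
        expected = antibody.coord.copy()
        expected[movers] = T.apply(expected[movers])
        np.testing.assert_allclose(out.coord, expected, atol=1e-9)
        # atoms outside the moving set are untouched
        np.testing.assert_array_equal(out.coord[~movers], antibody.coord[~movers])

    @settings(max_examples=20, deadline=None)
    @given(
        delta=st.floats(-180, 180),
        res=st.integers(1, 3),
        angle=st.sampled_from(["phi", "psi"]),
    )
    def test_rigid_sets_keep_internal_distances(self, antibody, delta, res, angle):
        # bond lengths, angles and all intra-set distances are conserved
        if angle == "phi" and res == 1:
            return  # phi of the first residue lacks the preceding C
        out = ax.apply_torsion(antibody, ("B", res, angle), delta)
        moved = ~np.isclose(out.coord, antibody.coord).all(axis=1)
        for mask in (moved, ~moved):
            idx = np.flatnonzero(mask)
            if len(idx) < 2:
                continue
            sub = idx[:: max(1, len(idx) // 40)]  # thin for speed
            before = cdist(antibody.coord[sub], antibody.coord[sub])
            after = cdist(out.coord[sub], out.coord[sub])
            np.testing.assert_allclose(after, before, atol=1e-9)

    def test_missing_backbone_errors(self, fab):
        with pytest.raises(ValidationError):
            ax.apply_torsion(fab, ("A", 1, "phi"), 10.0)


def test_transform_invariants():
    T = rotation_about_axis([1.0, 2.0, 3.0], [0.0, 0.0, 1.0], 73.0)
    assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)
    xyz = np.random.default_rng(0).uniform(-10, 10, (20, 3))
    np.testing.assert_allclose(T.inverse().apply(T.apply(xyz)), xyz, atol=1e-9)
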