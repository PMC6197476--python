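"""Scattering calculators and 1-D analyses against closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import absaxs as ax
from absaxs.errors import FitError, ValidationError
from absaxs.saxscalc import FormFactorTable, fit_qgrid

from conftest import sphere_form_factor


def _points(xyz, element="C"):
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    n = len(xyz)
    return ax.Structure(
        serial=np.arange(1, n + 1),
        chain_id=np.full(n, "A"),
        res_id=np.arange(1, n + 1),
        res_name=np.full(n, "ALA"),
        atom_name=np.full(n, "CA"),
        element=np.full(n, element),
        coord=xyz,
    )


class TestDebyeProfile:
    def test_single_atom_unit_factor(self):
        prof = ax.debye_profile(_points([[0, 0, 0]]), np.linspace(0, 0.3, 7))
        np.testing.assert_allclose(prof.intensity, 1.0)

    def test_two_atom_closed_form(self):
        # I(Q) = 2 (1 + sin(Qd)/(Qd)) for two unit scatterers d apart
        prof = ax.debye_profile(_points([[0, 0, 0], [10, 0, 0]]), np.array([0.1]))
        assert prof.intensity[0] == pytest.approx(2.0 * (1.0 + np.sin(1.0) / 1.0),
                                                  rel=1e-12)

    def test_forward_intensity_is_total_scattering_squared(self, fab):
        prof = ax.debye_profile(fab, np.array([0.0]))
        assert prof.intensity[0] == pytest.approx(fab.n_atoms**2, rel=1e-12)

    def test_sphere_cloud_matches_analytic_form(self, random_ball):
        # normalised intensity vs the sphere form factor; Monte-Carlo noise
        # of a 3000-point cloud is ~0.003 on this scale in the tail
        radius = 30.0
        q = np.linspace(0.01, 4.0 / radius, 15)
        prof = ax.debye_profile(random_ball, q)
        got = prof.intensity / random_ball.n_atoms**2
        np.testing.assert_allclose(got, sphere_form_factor(q, radius), atol=0.01)

    def test_atomic_mode_f0_is_electron_count(self):
        ff = FormFactorTable(mode="atomic")
        f = ff.factors(np.array(["C", "N", "O", "S", "H"]), np.array([0.0]))
        np.testing.assert_allclose(f[:, 0], [6, 7, 8, 16, 1], atol=0.01)

    def test_negative_q_errors(self, fab):
        with pytest.raises(ValidationError):
            ax.debye_profile(fab, np.array([-0.1]))


class TestGoldenVectorProfile:
    def test_single_atom_independent_of_directions(self):
        s = _points([[3, 2, 1]])
        q = np.linspace(0.01, 0.3, 5)
        for m in (1, 7, 99):
            prof = ax.golden_vector_profile(s, q, n_vectors=m)
            np.testing.assert_allclose(prof.intensity, 1.0, rtol=1e-12)

    def test_agrees_with_debye_at_299_vectors(self, antibody):
        q = np.linspace(0.01, 0.2, 20)
        debye = ax.debye_profile(antibody, q)
        golden = ax.golden_vector_profile(antibody, q, n_vectors=299)
        np.testing.assert_allclose(golden.intensity, debye.intensity, rtol=0.01)

    def test_quadrature_converges_on_average(self, antibody):
        q = np.linspace(0.01, 0.2, 10)
        ref = ax.debye_profile(antibody, q).intensity
        mean_dev = []
        for m in (35, 70, 140, 280):
            got = ax.golden_vector_profile(antibody, q, n_vectors=m).intensity
            mean_dev.append(np.mean(np.abs(got / ref - 1.0)))
        assert mean_dev[-1] < mean_dev[0]
        # average deviation decreases as direction count doubles
        assert all(b < a * 1.5 for a, b in zip(mean_dev, mean_dev[1:]))


class TestGuinier:
    def test_exact_guinier_curve(self):
        q = np.linspace(0.001, 0.1, 200)
        prof = ax.ScatteringProfile(q, 100.0 * np.exp(-(q**2) * 50.0**2 / 3.0))
        res = ax.guinier_fit(prof)
        assert res.rg == pytest.approx(50.0, abs=1e-6)
        assert res.i0 == pytest.approx(100.0, abs=1e-6)

    def test_window_honours_qmaxrg_limit(self, ball_profile):
        res = ax.guinier_fit(ball_profile, qmax_rg_limit=1.3)
        dq = ball_profile.q[1] - ball_profile.q[0]
        assert res.qmax_rg <= 1.3 + dq * res.rg  # grid-resolution slack
        assert res.qmin_rg == pytest.approx(ball_profile.q[0] * res.rg)

    def test_sphere_cloud_rg(self, ball_profile):
        res = ax.guinier_fit(ball_profile)
        assert res.rg == pytest.approx(30.0 * np.sqrt(3.0 / 5.0), rel=0.02)

    def test_noiseless_debye_rg_matches_coordinates(self, antibody):
        q = np.linspace(0.002, 0.2, 150)
        prof = ax.debye_profile(antibody, q)
        res = ax.guinier_fit(prof, qmax_rg_limit=1.0)
        assert res.rg == pytest.approx(ax.radius_of_gyration(antibody), rel=0.01)

    def test_flat_profile_errors(self):
        q = np.linspace(0.01, 0.1, 30)
        with pytest.raises(FitError):
            ax.guinier_fit(ax.ScatteringProfile(q, np.full(30, 5.0) + q))


class TestPairDistribution:
    def test_two_atoms(self):
        pd_ = ax.pair_distribution(_points([[0, 0, 0], [10, 0, 0]]), bin_width=1.0)
        assert pd_.dmax == pytest.approx(10.0)
        occupied = np.flatnonzero(pd_.p > 0)
        assert len(occupied) == 1
        lo = pd_.r[occupied[0]] - 0.5
        assert lo <= 10.0 <= lo + 1.0

    def test_moment_identity_gives_rg(self, antibody):
        # Rg^2 = Integral r^2 p(r) dr / 2 up to the O(1/N) self-pair bias
        pd_ = ax.pair_distribution(antibody, bin_width=0.5)
        assert pd_.rg() == pytest.approx(
            ax.radius_of_gyration(antibody), rel=0.01
        )

    def test_sphere_pddf_closed_form(self, random_ball):
        # p(r) of a uniform sphere ~ r^2 (1 - 3x/2 + x^3/2), x = r / (2R)
        pd_ = ax.pair_distribution(random_ball, bin_width=1.0)
        radius = 30.0
        x = pd_.r / (2 * radius)
        expected = pd_.r**2 * np.clip(1 - 1.5 * x + 0.5 * x**3, 0, None)
        expected[x > 1] = 0.0
        expected /= expected.sum() * pd_.bin_width
        mask = expected > expected.max() * 0.05
        np.testing.assert_allclose(pd_.p[mask], expected[mask], rtol=0.1)

    def test_unit_area(self, fab):
        pd_ = ax.pair_distribution(fab, bin_width=0.7)
        assert pd_.p.sum() * pd_.bin_width == pytest.approx(1.0, rel=1e-12)

    def test_single_atom_errors(self):
        with pytest.raises(ValidationError):
            ax.pair_distribution(_points([[0, 0, 0]]))


class TestKratky:
    def test_unit_intensity_gives_q_squared(self):
        q = np.linspace(0.0, 0.3, 31)
        table = ax.kratky_transform(ax.ScatteringProfile(q, np.ones_like(q)))
        np.testing.assert_allclose(table[:, 1], q**2)
        assert table[0, 1] == 0.0

    def test_gaussian_peak_at_sqrt3_over_rg(self):
        rg = 40.0
        q = np.linspace(0.001, 0.12, 600)
        prof = ax.ScatteringProfile(q, np.exp(-(q**2) * rg**2 / 3.0))
        table = ax.kratky_transform(prof)
        qpeak = table[np.argmax(table[:, 1]), 0]
        assert qpeak == pytest.approx(np.sqrt(3.0) / rg, abs=q[1] - q[0])


class TestReducedChi2:
    def _profile(self, scale=1.0, sigma_scale=1.0, offset_in_sigma=0.0):
        q = np.linspace(0.005, 0.25, 60)
        i = 1000.0 * np.exp(-(q**2) * 900.0) + 5.0
        sigma = 0.02 * i * sigma_scale
        return ax.ScatteringProfile(q, scale * (i + offset_in_sigma * 0.02 * i), sigma)

    def test_identical_profiles_fixed_scale(self):
        p = self._profile()
        cfg = ax.FitConfig(scale_mode="fixed")
        chi2, scale = ax.reduced_chi2(p, p, cfg)
        assert chi2 == 0.0 and scale == 1.0

    def test_scale_invariance_when_fitted(self):
        exp = self._profile()
        model = ax.ScatteringProfile(exp.q, 3.7 * exp.intensity)
        chi2, scale = ax.reduced_chi2(model, exp, ax.FitConfig(scale_mode="fitted"))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert scale == pytest.approx(1.0 / 3.7, rel=1e-12)

    def test_one_sigma_offset_gives_exactly_one(self):
        # model = experiment + 1 sigma at each of the 19 grid points, fixed scale
        exp = self._profile()
        model = ax.ScatteringProfile(exp.q, exp.intensity + exp.sigma)
        cfg = ax.FitConfig(scale_mode="fixed")
        chi2, _ = ax.reduced_chi2(model, exp, cfg)
        assert chi2 == pytest.approx(1.0, rel=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(factor=st.floats(0.01, 100.0))
    def test_invariant_under_joint_experiment_rescaling(self, factor):
        exp = self._profile()
        model = self._profile(offset_in_sigma=0.7)
        cfg = ax.FitConfig()
        chi2_a, _ = ax.reduced_chi2(model, exp, cfg)
        scaled = ax.ScatteringProfile(
            exp.q, factor * exp.intensity, factor * exp.sigma
        )
        chi2_b, _ = ax.reduced_chi2(model, scaled, cfg)
        assert chi2_b == pytest.approx(chi2_a, rel=1e-9)

    def test_grid_must_be_covered(self):
        exp = self._profile()
        model = ax.ScatteringProfile(
            np.linspace(0.05, 0.25, 30), np.ones(30)
        )
        with pytest.raises(ValidationError):
            ax.reduced_chi2(model, exp)

    def test_sigma_policy_required(self):
        q = np.linspace(0.005, 0.25, 30)
        exp = ax.ScatteringProfile(q, np.ones(30))
        model = ax.ScatteringProfile(q, np.ones(30))
        with pytest.raises(ValidationError):
            ax.reduced_chi2(model, exp)
        chi2, _ = ax.reduced_chi2(
            model, exp, ax.FitConfig(constant_sigma=0.5, scale_mode="fixed")
        )
        assert chi2 == 0.0

    def test_default_grid_is_19_points_to_019(self):
        grid = fit_qgrid(ax.FitConfig())
        assert len(grid) == 19
        assert grid[0] == pytest.approx(0.01)
        assert grid[-1] == pytest.approx(0.19)
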