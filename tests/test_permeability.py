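"""Diffusion estimation and solubility-diffusion permeability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import memperm as mp
from memperm.fes import EstimationError


def _profile_fes(F, z, thermo, error=None, mask=None, bulk_cut=None):
    n = len(z)
    return mp.FreeEnergySurface(
        (np.asarray(z, float),), np.asarray(F, float),
        np.zeros(n) if error is None else np.asarray(error, float),
        np.ones(n, bool) if mask is None else mask, "none", thermo,
        bulk_cut, ("z",))


class TestISDClosedForms:
    def test_flat_profile_P_equals_D_over_L(self, thermo):
        z = np.linspace(-25, 25, 501)
        fes = _profile_fes(np.zeros_like(z), z, thermo)
        res = mp.isd_permeability(fes, lambda zz: np.full_like(zz, 0.5))
        assert res.P == pytest.approx(0.5 / 50.0 * 1e4, rel=1e-10)
        assert res.P == pytest.approx(100.0, rel=1e-10)

    def test_square_barrier_closed_form(self, thermo):
        B, w, D0 = 11.0, 10.0, 0.5
        z = np.arange(-25, 25 + 1e-9, 0.005)
        F = np.where(np.abs(z) <= w / 2, B, 0.0)
        fes = _profile_fes(F, z, thermo)
        res = mp.isd_permeability(fes, lambda zz: np.full_like(zz, D0))
        beta = thermo.beta
        R_exact = (40.0 + w * np.exp(beta * B)) / D0     # ps/Å
        P_exact = 1.0 / R_exact * 1e4
        assert res.P == pytest.approx(P_exact, rel=1e-3)

    def test_resistance_additivity(self, thermo):
        rng = np.random.default_rng(8)
        z = np.linspace(-20, 20, 401)
        F = 8.0 * np.exp(-z ** 2 / 18.0) + 0.2 * np.sin(z)
        F -= F[0]
        F[np.abs(z) > 18] *= 0.0
        fes = _profile_fes(F, z, thermo)
        D = lambda zz: 0.4 + 0.1 * np.cos(zz / 7.0)
        full = mp.isd_permeability(fes, D)
        for zc in rng.choice(z[50:-50], 3, replace=False):
            i = int(np.argmin(np.abs(z - zc)))
            left = np.trapezoid(np.exp(thermo.beta * F[: i + 1]) /
                                D(z[: i + 1]), z[: i + 1])
            right = np.trapezoid(np.exp(thermo.beta * F[i:]) / D(z[i:]),
                                 z[i:])
            assert (left + right) == pytest.approx(1e4 / full.P,
                                                   rel=1e-10)

    def test_resistance_profile_integrates_to_inverse_P(self, thermo):
        z = np.linspace(-15, 15, 301)
        F = 5.0 * np.exp(-z ** 2 / 8.0)
        fes = _profile_fes(F, z, thermo)
        res = mp.isd_permeability(fes, lambda zz: np.full_like(zz, 0.5))
        # resistance in s·cm⁻¹·Å⁻¹ integrates over Å to 1/P in s/cm
        assert np.trapezoid(res.resistance_profile, res.z) == pytest.approx(
            1.0 / res.P, rel=1e-10)

    def test_P_decreases_with_barrier_height(self, thermo):
        z = np.linspace(-20, 20, 401)
        Ps = []
        for B in (5.0, 10.0, 15.0):
            F = B * np.exp(-z ** 2 / 8.0)
            fes = _profile_fes(F, z, thermo)
            Ps.append(mp.isd_permeability(
                fes, lambda zz: np.full_like(zz, 0.5)).P)
        assert Ps[0] > Ps[1] > Ps[2]

    def test_unreferenced_profile_rejected(self, thermo):
        z = np.linspace(-10, 10, 101)
        fes = _profile_fes(np.full(101, 5.0), z, thermo)
        with pytest.raises(ValueError, match="bulk-referenced"):
            mp.isd_permeability(fes, lambda zz: np.full_like(zz, 0.5))

    def test_error_propagates_from_F_uncertainty(self, thermo):
        z = np.linspace(-10, 10, 201)
        F = 6.0 * np.exp(-z ** 2 / 8.0)
        res0 = mp.isd_permeability(_profile_fes(F, z, thermo),
                                   lambda zz: np.full_like(zz, 0.5))
        res1 = mp.isd_permeability(
            _profile_fes(F, z, thermo, error=np.full(201, 0.5)),
            lambda zz: np.full_like(zz, 0.5))
        assert res0.error == 0.0
        assert res1.error > 0.0


class TestDiffusionEstimation:
    def test_ou_window_recovers_D(self, flat_surface, constant_diffusion,
                                  thermo):
        surf = flat_surface.with_restraint(10.0, 0.0)
        traj = mp.simulate_overdamped(surf, constant_diffusion, thermo,
                                      dt=0.01, n_steps=1_000_000, seed=11,
                                      z_max=np.inf)
        D, err, tau = mp.estimate_D_at(traj)
        assert D == pytest.approx(0.5, rel=0.15)
        assert tau == pytest.approx(thermo.kT / 10.0 / 0.5, rel=0.3)

    def test_integrated_exponential_acf_identity(self):
        """For ACF = var·e^{−t/τ}, var²/∫ACF = var/τ."""
        from memperm.permeability import _integrate_acf
        dt, tau, var = 0.001, 0.5, 2.0
        t = np.arange(0, 30 * tau, dt)
        acf = var * np.exp(-t / tau)
        integral, _ = _integrate_acf(acf, dt)
        assert var ** 2 / integral == pytest.approx(var / tau, rel=0.02)

    def test_longer_window_shrinks_error(self, flat_surface,
                                         constant_diffusion, thermo):
        surf = flat_surface.with_restraint(10.0, 0.0)
        errs = []
        for n in (100_000, 800_000):
            traj = mp.simulate_overdamped(surf, constant_diffusion, thermo,
                                          dt=0.01, n_steps=n, seed=13,
                                          z_max=np.inf)
            errs.append(mp.estimate_D_at(traj)[1])
        assert errs[1] < errs[0]

    def test_nonstationary_input_rejected(self, thermo):
        t = 0.01 * np.arange(1, 20001)
        rng = np.random.default_rng(2)
        values = 0.05 * np.cumsum(rng.standard_normal(20000))  # random walk
        traj = mp.CVTrajectory(t, values, thermo, 0.01)
        with pytest.raises(EstimationError, match="non-stationary"):
            mp.estimate_D_at(traj)


@pytest.fixture(scope="module")
def windows(flat_surface, thermo):
    dm = mp.DiffusionModel("smooth-profile", 0.6, 0.2, 2.0)
    out = []
    for i, z0 in enumerate(np.linspace(-12, 12, 9)):
        surf = flat_surface.with_restraint(10.0, z0)
        traj = mp.simulate_overdamped(surf, dm, thermo, dt=0.01,
                                      n_steps=300_000, seed=100 + i,
                                      x0=[z0], z_max=15.0)
        out.append((float(z0), traj))
    return out


class TestDProfile:
    def test_two_level_profile_recovered(self, windows):
        dm = mp.DiffusionModel("smooth-profile", 0.6, 0.2, 2.0)
        prof = mp.build_D_profile(windows)
        rel = np.abs(prof.D - dm(prof.z)) / dm(prof.z)
        assert np.all(rel < 0.2)

    def test_symmetrized_profile_is_even(self, windows):
        prof = mp.build_D_profile(windows)
        np.testing.assert_allclose(prof(prof.z), prof(-prof.z), atol=1e-12)

    def test_too_few_windows_rejected(self, windows):
        with pytest.raises(ValueError, match="5 window"):
            mp.build_D_profile(windows[:4])

    def test_coverage_gap_warns(self, windows):
        sparse = windows[:3] + windows[7:]
        with pytest.warns(UserWarning, match="coverage gap"):
            mp.build_D_profile(sparse)


class TestField:
    def test_published_field_inside_printed_window(self):
        """2·E·μ for E = 10 mV/Å, μ = 5.8 D lands in 2–3 kJ/mol."""
        scale = mp.field_energy_scale(mp.FieldSpec(E=10.0, mu=5.8))
        assert 2.0 < scale < 3.0
        assert scale == pytest.approx(2.33, abs=0.01)

    def test_zero_field_zero_energy(self):
        assert mp.field_energy_scale(mp.FieldSpec(E=0.0, mu=5.8)) == 0.0

    @given(st.floats(0.1, 50.0), st.floats(0.1, 20.0))
    @settings(max_examples=25, deadline=None)
    def test_linearity_in_mu_and_E(self, E, mu):
        one = mp.field_energy_scale(mp.FieldSpec(E=E, mu=mu))
        assert mp.field_energy_scale(mp.FieldSpec(E=E, mu=2 * mu)) == \
            pytest.approx(2 * one, rel=1e-12)
        assert mp.field_energy_scale(mp.FieldSpec(E=2 * E, mu=mu)) == \
            pytest.approx(2 * one, rel=1e-12)

    def test_zero_coupling_leaves_surface_unchanged(self, thermo):
        z = np.linspace(-10, 10, 101)
        fes = _profile_fes(5 * np.exp(-z ** 2 / 8.0), z, thermo)
        out = mp.apply_field_tilt(fes, mp.FieldSpec(), lambda zz: 0.0 * zz)
        np.testing.assert_array_equal(out.F, fes.F)

    def test_antisymmetric_coupling_splits_minima(self, double_well,
                                                  thermo):
        """Constant-magnitude odd coupling splits the two wells by 2·E·μ·c0."""
        from conftest import fes_from_surface
        c0 = 0.8
        fes = fes_from_surface(double_well, 6.0, 120, thermo)
        field = mp.FieldSpec(E=10.0, mu=5.8)
        out = mp.apply_field_tilt(fes, field,
                                  lambda zz: c0 * np.sign(zz))
        emu = mp.field_energy_scale(field) / 2
        i = np.argmin(np.abs(fes.axes[0] - double_well.z_min))
        j = np.argmin(np.abs(fes.axes[0] + double_well.z_min))
        split = out.F[j] - out.F[i]
        assert split == pytest.approx(2 * emu * c0, abs=1e-10)

    def test_perturbation_bounded_by_half_energy_scale(self, thermo):
        z = np.linspace(-10, 10, 201)
        fes = _profile_fes(np.zeros_like(z), z, thermo)
        field = mp.FieldSpec(E=10.0, mu=5.8)
        out = mp.apply_field_tilt(fes, field, lambda zz: np.tanh(zz))
        bound = mp.field_energy_scale(field) / 2
        assert np.abs(out.F - fes.F).max() <= bound + 1e-12

    def test_excessive_coupling_rejected(self, thermo):
        z = np.linspace(-5, 5, 51)
        fes = _profile_fes(np.zeros_like(z), z, thermo)
        with pytest.raises(ValueError, match="coupling"):
            mp.apply_field_tilt(fes, mp.FieldSpec(), lambda zz: 1.5 + 0 * zz)


class TestEndToEnd:
    def test_pipeline_P_within_factor_two_of_analytic(
            self, cq0_symmetrized_fes, cq0_params, thermo):
        """Reconstructed-FES permeability vs the analytic-landscape value."""
        prof = mp.marginal_z(cq0_symmetrized_fes, reference="bulk-zero",
                             bulk_cut=12.0)
        D0 = lambda zz: np.full_like(zz, 0.5)
        res = mp.isd_permeability(prof, D0, (-13.0, 13.0))
        # analytic reference: same marginal built from the exact surface
        from conftest import fes_from_surface
        surface = mp.make_membrane_potential(cq0_params)
        exact = fes_from_surface(surface, 15.0, 60, thermo, bulk_cut=12.0)
        prof_exact = mp.marginal_z(exact, reference="bulk-zero",
                                   bulk_cut=12.0)
        res_exact = mp.isd_permeability(prof_exact, D0, (-13.0, 13.0))
        assert res.P == pytest.approx(res_exact.P, rel=1.0)
        assert 0.5 < res.P / res_exact.P < 2.0
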