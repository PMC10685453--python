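"""FES estimation: reweighting, block errors, symmetrization, cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import memperm as mp
from memperm.fes import EstimationError

from conftest import fes_from_surface


def _fes_1d(F, thermo, mask=None, error=None, lim=None):
    F = np.asarray(F, float)
    n = len(F)
    lim = n / 4 if lim is None else lim
    ax = (np.arange(n) + 0.5) * (2 * lim / n) - lim
    mask = np.ones(n, bool) if mask is None else np.asarray(mask, bool)
    error = np.zeros(n) if error is None else np.asarray(error, float)
    return mp.FreeEnergySurface((ax,), F, error, mask, "none", thermo)


class TestReweight:
    def test_unbiased_reduces_to_histogram(self, double_well,
                                           constant_diffusion, thermo):
        traj = mp.simulate_overdamped(double_well, constant_diffusion,
                                      thermo, dt=0.02, n_steps=200_000,
                                      seed=21, z_max=6.0, record_every=10)
        fes = mp.reweight_to_fes(traj, None, None, burn_in=0.0, bins=16,
                                 cv_range=6.0)
        hist, _ = np.histogram(traj.values[:, 0], bins=16, range=(-6, 6))
        expected = -thermo.kT * np.log(hist[hist > 0])
        expected -= expected.min()
        np.testing.assert_allclose(fes.F[fes.mask], expected, atol=1e-9)

    def test_double_well_barrier_recovered(self, double_well_run):
        run = double_well_run
        fes = mp.reweight_to_fes(run["traj"], run["ledger"], run["rw"],
                                 burn_in=1.0 / 9.0, bins=64, cv_range=8.0)
        ax = fes.axes[0]
        well = np.nanmin(fes.F[fes.mask])
        barrier = np.nanmin(fes.F[(np.abs(ax) < 0.6) & fes.mask]) - well
        assert barrier == pytest.approx(10.0, abs=1.0)

    def test_burn_in_stability(self, double_well_run):
        run = double_well_run

        def barrier(burn):
            fes = mp.block_error(run["traj"], run["ledger"], run["rw"],
                                 burn_in=burn, bins=64, cv_range=8.0)
            ax = fes.axes[0]
            b = np.nanmin(fes.F[(np.abs(ax) < 0.6) & fes.mask]) \
                - np.nanmin(fes.F[fes.mask])
            center = np.nanargmin(np.where(np.abs(ax) < 0.6, fes.F, np.nan))
            return b, fes.error[center]

        b0, e0 = barrier(0.0)
        b1, e1 = barrier(0.1)
        assert abs(b0 - b1) < 3 * np.hypot(e0, e1) + 0.2

    def test_too_few_frames_raises(self, double_well, constant_diffusion,
                                   thermo):
        traj = mp.simulate_overdamped(double_well, constant_diffusion,
                                      thermo, dt=0.02, n_steps=1000, seed=1,
                                      z_max=6.0)
        with pytest.raises(EstimationError, match="frames"):
            mp.reweight_to_fes(traj, None, None, burn_in=0.0, bins=200,
                               cv_range=6.0)

    def test_reference_invariance_under_bias_offset(self, double_well_run):
        """A constant added to the bias only shifts F by a constant."""
        run = double_well_run
        traj2 = mp.CVTrajectory(run["traj"].times, run["traj"].values,
                                run["traj"].thermo, run["traj"].stride,
                                v_bias=run["traj"].v_bias + 7.5)
        f1 = mp.reweight_to_fes(run["traj"], run["ledger"], run["rw"],
                                bins=64, cv_range=8.0)
        f2 = mp.reweight_to_fes(traj2, run["ledger"], run["rw"],
                                bins=64, cv_range=8.0)
        assert np.nanmax(np.abs(f1.F[f1.mask] - f2.F[f2.mask])) < 1e-6


class TestBlockError:
    def test_identical_blocks_give_zero_error(self, thermo):
        rng = np.random.default_rng(5)
        block = rng.uniform(-3, 3, size=1200)
        values = np.tile(block, 3)
        traj = mp.CVTrajectory(0.1 * np.arange(1, len(values) + 1),
                               values, thermo, 0.1)
        fes = mp.block_error(traj, None, None, n_blocks=3, burn_in=0.0,
                             bins=12, cv_range=3.0)
        assert np.nanmax(fes.error[np.isfinite(fes.error)]) < 1e-9

    def test_default_is_three_blocks(self):
        import inspect
        assert inspect.signature(mp.block_error).parameters[
            "n_blocks"].default == 3

    def test_three_vs_six_blocks_same_magnitude(self, double_well_run):
        run = double_well_run
        kw = dict(burn_in=1.0 / 9.0, bins=32, cv_range=8.0)
        e3 = mp.block_error(run["traj"], run["ledger"], run["rw"],
                            n_blocks=3, **kw)
        e6 = mp.block_error(run["traj"], run["ledger"], run["rw"],
                            n_blocks=6, **kw)
        both = np.isfinite(e3.error) & np.isfinite(e6.error) \
            & (e3.error > 0) & (e6.error > 0) & (np.abs(e3.axes[0]) < 7.0)
        ratio = e3.error[both] / e6.error[both]
        assert 0.3 < np.median(ratio) < 3.0
        # individual bins fluctuate (few-sample variances) but stay sane
        assert np.quantile(ratio, 0.9) < 5.0
        assert np.quantile(ratio, 0.1) > 0.1


class TestSymmetrize:
    def test_symmetric_surface_is_fixed_point(self, double_well, thermo):
        fes = fes_from_surface(double_well, 6.0, 24, thermo)
        out = mp.symmetrize(fes)
        np.testing.assert_allclose(out.F, fes.F, atol=1e-12)

    def test_step_profile_closed_form(self, thermo):
        X = 5.0
        F = np.where(np.arange(20) < 10, 0.0, X)
        fes = _fes_1d(F, thermo)
        out = mp.symmetrize(fes)
        beta = thermo.beta
        expected = -np.log((1 + np.exp(-beta * X)) / 2) / beta
        np.testing.assert_allclose(out.F, expected, atol=1e-10)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent_on_random_surfaces(self, seed):
        thermo = mp.ThermoState(310.0)
        rng = np.random.default_rng(seed)
        F = rng.uniform(0, 30, size=18)
        mask = rng.uniform(size=18) > 0.2
        if not mask.any():
            mask[0] = True
        fes = _fes_1d(F, thermo, mask=mask)
        once = mp.symmetrize(fes)
        twice = mp.symmetrize(once)
        both = once.mask
        np.testing.assert_allclose(twice.F[both], once.F[both], atol=1e-10)

    def test_half_visited_copies_mirror(self, thermo):
        F = np.arange(10.0)
        mask = np.zeros(10, bool)
        mask[:5] = True
        out = mp.symmetrize(_fes_1d(F, thermo, mask=mask))
        assert np.all(out.mask)
        np.testing.assert_allclose(out.F[5:], F[:5][::-1], atol=1e-12)

    def test_asymmetric_axis_rejected(self, thermo):
        ax = np.linspace(0.0, 5.0, 10)
        fes = mp.FreeEnergySurface((ax,), np.zeros(10), np.zeros(10),
                                   np.ones(10, bool), "none", thermo)
        with pytest.raises(ValueError, match="symmetric"):
            mp.symmetrize(fes)


class TestAsymmetry:
    def test_symmetric_surface_zero(self, double_well, thermo):
        fes = fes_from_surface(double_well, 6.0, 24, thermo)
        assert mp.asymmetry(fes) == pytest.approx(0.0, abs=1e-12)

    def test_single_raised_bin(self, thermo):
        F = np.zeros(20)
        F[3] += 2.0
        assert mp.asymmetry(_fes_1d(F, thermo)) == pytest.approx(2.0)

    def test_converged_run_asymmetry_within_block_noise(self,
                                                        double_well_run):
        run = double_well_run
        fes = mp.block_error(run["traj"], run["ledger"], run["rw"],
                             burn_in=1.0 / 9.0, bins=32, cv_range=8.0)
        interior = np.abs(fes.axes[0]) < 7.0
        sub = fes.copy()
        sub.mask = fes.mask & interior
        err = fes.error[np.isfinite(fes.error) & interior]
        assert mp.asymmetry(sub) <= 6 * np.sqrt(2) * err.mean() + 0.5


class TestBiasBasedFES:
    def test_flat_bias_flat_fes(self, thermo):
        ledger = mp.HillsLedger(1, 20.0, thermo, 2.0)
        grid = mp.BiasGrid.from_spacing([-4.0], [4.0], 0.5)
        fes = mp.bias_based_fes(ledger, grid)
        assert np.all(fes.F == 0.0)

    def test_prefactor_is_gamma_over_gamma_minus_one(self, thermo):
        ledger = mp.HillsLedger(1, 20.0, thermo, 2.0)
        ledger.append(mp.GaussianKernel([0.0], [0.5], 1.0, 2.0))
        grid = mp.BiasGrid.from_spacing([-4.0], [4.0], 0.5)
        fes = mp.bias_based_fes(ledger, grid)
        V = mp.evaluate_bias(ledger, grid, 2.0).values
        np.testing.assert_allclose(fes.F - fes.F.min(),
                                   -(20.0 / 19.0) * V
                                   + (20.0 / 19.0) * V.max(), atol=1e-10)

    def test_agrees_with_reweighting_on_converged_run(self, double_well_run):
        """Dual-route estimator consistency on interior, well-sampled bins."""
        run = double_well_run
        fes = mp.block_error(run["traj"], run["ledger"], run["rw"],
                             burn_in=1.0 / 9.0, bins=64, cv_range=8.0)
        bgrid = mp.BiasGrid(np.array([fes.axes[0][0]]),
                            np.array([fes.axes[0][-1]]), np.array([64]))
        bb = mp.bias_based_fes(run["ledger"], bgrid)
        interior = fes.mask & (np.abs(fes.axes[0]) < 7.0)
        d = fes.F[interior] - bb.F[interior]
        d -= d.mean()
        tol = np.maximum(1.5, 3 * np.nan_to_num(fes.error[interior], nan=0.0))
        assert np.all(np.abs(d) <= tol)

    def test_barrier_agreement(self, double_well_run):
        run = double_well_run
        fes = mp.reweight_to_fes(run["traj"], run["ledger"], run["rw"],
                                 burn_in=1.0 / 9.0, bins=64, cv_range=8.0)
        ax = fes.axes[0]
        b_rw = np.nanmin(fes.F[(np.abs(ax) < 0.6) & fes.mask]) \
            - np.nanmin(fes.F[fes.mask])
        bgrid = mp.BiasGrid(np.array([ax[0]]), np.array([ax[-1]]),
                            np.array([64]))
        bb = mp.bias_based_fes(run["ledger"], bgrid)
        b_bb = np.nanmin(bb.F[np.abs(ax) < 0.6]) - bb.F.min()
        assert abs(b_rw - b_bb) < 1.5


class TestMarginalZ:
    def test_matches_weighted_histogram_oracle(self, cq0_params, thermo):
        """z-projection equals −kT·ln of a Boltzmann-weighted z histogram."""
        surface = mp.make_membrane_potential(cq0_params)
        fes = fes_from_surface(surface, 15.0, 60, thermo, bulk_cut=12.0)
        prof = mp.marginal_z(fes, reference="min-zero")
        beta = thermo.beta
        z = fes.z_of_bins().ravel()
        w = np.exp(-beta * (fes.F.ravel() - fes.F.min()))
        lo = prof.axes[0][0] - prof.spacing[0] / 2
        hi = prof.axes[0][-1] + prof.spacing[0] / 2
        hist, _ = np.histogram(z, bins=len(prof.axes[0]), range=(lo, hi),
                               weights=w)
        Fo = np.full(len(hist), np.nan)
        Fo[hist > 0] = -np.log(hist[hist > 0]) / beta
        Fo -= np.nanmin(Fo)
        np.testing.assert_allclose(prof.F[prof.mask], Fo[hist > 0], atol=1e-8)
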