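"""Shared fixtures: analytic landscapes and reference metadynamics runs.

The expensive biased runs are session-scoped so the estimator, path and
acceptance tests share one trajectory each.
"""

from __future__ import annotations

import numpy as np
import pytest

import memperm as mp


@pytest.fixture(scope="session")
def thermo():
    return mp.ThermoState(310.0)


@pytest.fixture(scope="session")
def flat_surface():
    return mp.GaussianSurface(1, np.zeros((0, 1)), [], [], [])


@pytest.fixture(scope="session")
def constant_diffusion():
    return mp.DiffusionModel("constant", 0.5, 0.5, 3.0)


@pytest.fixture(scope="session")
def double_well():
    """1D double well: 10 kJ/mol barrier between minima at ±3 Å."""
    params = mp.ModelPotential(
        dimensionality=1, interfacial_min_depth=10.0, core_barrier_height=10.0,
        interfacial_min_position=3.0,
        widths=mp.FeatureWidths(well=1.0, barrier=1.5, coupling=1.0))
    return mp.make_membrane_potential(params)


@pytest.fixture(scope="session")
def double_well_run(double_well, constant_diffusion, thermo):
    """40 ns well-tempered metadynamics on the 1D double well (fixed seed)."""
    grid = mp.BiasGrid.from_spacing([-8.0], [8.0], 0.05)
    traj, ledger, rw = mp.run_wtmetad(
        double_well, constant_diffusion, thermo, dt=0.02, n_steps=2_000_000,
        seed=5, w0=1.2, sigma=0.5, pace=2.0, bias_factor=20.0, grid=grid,
        z_max=8.0, record_every=5)
    return {"surface": double_well, "traj": traj, "ledger": ledger,
            "rw": rw, "grid": grid, "z_max": 8.0}


@pytest.fixture(scope="session")
def cq0_params():
    """CQ0-like 2D landscape: interfacial depth 40, core rise 11 kJ/mol."""
    return mp.ModelPotential(
        dimensionality=2, interfacial_min_depth=40.0, core_barrier_height=11.0,
        interfacial_min_position=5.0, coupling_strength=25.0)


@pytest.fixture(scope="session")
def cq0_2d_run(cq0_params, constant_diffusion, thermo):
    """160 ns 2D metadynamics on the CQ0-like landscape (fixed seed)."""
    surface = mp.make_membrane_potential(cq0_params)
    grid = mp.BiasGrid.from_spacing([-15.0, -15.0], [15.0, 15.0], 0.1)
    traj, ledger, rw = mp.run_wtmetad(
        surface, constant_diffusion, thermo, dt=0.02, n_steps=8_000_000,
        seed=7, w0=1.2, sigma=0.5, pace=2.0, bias_factor=20.0, grid=grid,
        z_max=15.0, record_every=10)
    return {"surface": surface, "traj": traj, "ledger": ledger, "rw": rw,
            "grid": grid, "z_max": 15.0, "bulk_cut": 12.0}


@pytest.fixture(scope="session")
def cq0_symmetrized_fes(cq0_2d_run):
    fes = mp.block_error(cq0_2d_run["traj"], cq0_2d_run["ledger"],
                         cq0_2d_run["rw"], n_blocks=3, burn_in=1.0 / 9.0,
                         bins=60, cv_range=15.0, reference="bulk-zero",
                         bulk_cut=cq0_2d_run["bulk_cut"])
    return mp.symmetrize(fes).re_reference("bulk-zero",
                                           cq0_2d_run["bulk_cut"])


@pytest.fixture(scope="session")
def fast_pipeline_config():
    """Scaled-down full-pipeline configuration for smoke/determinism tests."""
    return {
        "seed": 91,
        "metad": {"n_steps": 300_000, "grid_spacing": 0.1,
                  "record_every": 10},
        "fes": {"bin_width": 1.0},
        "permeability": {"n_windows": 5, "window_steps": 40_000,
                         "window_record_every": 5},
    }


def fes_from_surface(surface, lim, n, thermo, bulk_cut=None, labels=None):
    """Exact FreeEnergySurface sampled from an analytic surface (no noise)."""
    ax = (np.arange(n) + 0.5) * (2 * lim / n) - lim
    if surface.dimensionality == 1:
        F = surface(ax)
        axes = (ax,)
    else:
        A, B = np.meshgrid(ax, ax, indexing="ij")
        pts = np.column_stack([A.ravel(), B.ravel()])
        F = surface.value(pts).reshape(A.shape)
        axes = (ax, ax)
    return mp.FreeEnergySurface(axes, F, np.zeros_like(F),
                                np.ones_like(F, bool), "none", thermo,
                                bulk_cut, labels)
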