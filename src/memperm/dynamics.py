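"""Overdamped Langevin sampler for collective-variable dynamics.

Euler–Maruyama integration of

    ds = [−β D(s) ∇F(s) + ∇D(s)] dt + sqrt(2 D(s) dt) dW     (Itô)

per CV coordinate, with the spurious drift ∇D included so that a
position-dependent diffusivity preserves the Boltzmann density.
Boundaries are reflective at |s| = z_max.  The sampler stands in for the
molecular-dynamics engine: it produces CV time series with the
equilibrium statistics that the downstream free-energy estimators assume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .landscapes import DiffusionModel, GaussianSurface
from .units import ThermoState

__all__ = ["CVTrajectory", "simulate_overdamped", "IntegrationError"]


class IntegrationError(RuntimeError):
    """Raised when a step diverges (|Δs| > 10 × smallest feature width)."""


@dataclass
class CVTrajectory:
    """Uniform-stride CV time series with its thermodynamic metadata.

    values has shape (n_frames, d) with d = 1 or 2; columns are
    (cv_cq,) for 1D or (cv_ring, cv_tail) for 2D, in Å.  ``v_bias``
    optionally stores the instantaneous metadynamics bias at each frame.
    """

    times: np.ndarray
    values: np.ndarray
    thermo: ThermoState
    stride: float
    seed: int | None = None
    v_bias: np.ndarray | None = None
    labels: tuple = field(default=None)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("times and values must have the same length")
        if np.any(~np.isfinite(self.values)) or np.any(~np.isfinite(self.times)):
            raise ValueError("trajectory contains non-finite entries")
        if len(self.times) > 1:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dts, self.stride, rtol=1e-8, atol=1e-10):
                raise ValueError("times must have the declared uniform stride")
        if not self.stride > 0:
            raise ValueError("stride must be positive")
        if self.labels is None:
            self.labels = ("cv_cq",) if self.dimensionality == 1 else (
                "cv_ring", "cv_tail")

    @property
    def dimensionality(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def _surface_arrays(surface: GaussianSurface):
    return (np.ascontiguousarray(surface.proj),
            np.ascontiguousarray(surface.centers),
            np.ascontiguousarray(surface.sigmas),
            np.ascontiguousarray(surface.amps),
            np.ascontiguousarray(surface.tilt),
            np.ascontiguousarray(surface.harm_k),
            np.ascontiguousarray(surface.harm_center))


def _feature_width(surface: GaussianSurface) -> float:
    widths = [float(s) for s in surface.sigmas]
    for k in surface.harm_k:
        if k > 0:
            widths.append(float(np.sqrt(1.0 / k)))
    return min(widths) if widths else 1.0


def _grad_scale(surface: GaussianSurface, kT: float) -> float:
    g = np.abs(surface.amps) * 0.6066 / surface.sigmas
    scale = float(g.sum()) + float(np.abs(surface.tilt).sum())
    # harmonic restraints: typical gradient at ~3 thermal standard deviations
    scale += float((3.0 * np.sqrt(surface.harm_k * kT)).sum())
    return scale


_EMPTY_GRID = (np.zeros(1), np.ones(1), np.ones(1, dtype=np.int64),
               np.zeros((1, 1)), np.zeros((1, 1)))


def simulate_overdamped(surface: GaussianSurface, diffusion: DiffusionModel,
                        thermo: ThermoState, dt: float, n_steps: int,
                        seed: int, bias=None, x0=None, z_max: float = 45.0,
                        record_every: int = 1,
                        chunk_steps: int = 65536) -> CVTrajectory:
    """Integrate overdamped Langevin dynamics on an analytic surface.

    Parameters
    ----------
    bias : callable, optional
        Live-bias hook called as ``bias(s, t)`` returning the bias force
        contribution −∇V(s, t) as an array of shape (d,).  When present
        the integration runs step-by-step in Python; metadynamics runs
        use the dedicated engine instead, which shares this integrator's
        compiled core.
    record_every : int
        Record every N-th step; the trajectory stride is record_every·dt.

    Same seed and parameters give a bit-identical trajectory.
    """
    diffusion.validate()
    if dt <= 0 or n_steps <= 0:
        raise ValueError("dt and n_steps must be positive")
    d = surface.dimensionality
    width = _feature_width(surface)
    d_max = max(diffusion.D_bulk, diffusion.D_core)
    drift = dt * d_max * _grad_scale(surface, thermo.kT) * thermo.beta
    if drift > 0.5 * width:
        warnings.warn(
            f"time step too coarse: predicted drift {drift:.3g} Å per step vs "
            f"feature width {width:.3g} Å; reduce dt", stacklevel=2)
    if x0 is None:
        x0 = np.full(d, getattr(surface, "z_min", 0.0))
    s = np.array(np.broadcast_to(np.asarray(x0, float), (d,)), dtype=float)
    max_step = 10.0 * width
    rng = np.random.default_rng(seed)
    arrays = _surface_arrays(surface)
    n_rec = n_steps // record_every
    out_pos = np.empty((n_rec, d))
    out_v = np.empty(n_rec)

    if bias is None:
        gmin, gspace, gshape, bias_v, bias_g = _EMPTY_GRID
        done = 0
        while done < n_steps:
            n = min(chunk_steps, n_steps - done)
            noise = rng.standard_normal((n, d))
            status, bad = _kernels.integrate_chunk(
                s, done, n, dt, thermo.beta, noise, *arrays,
                diffusion.form_code, diffusion.D_bulk, diffusion.D_core,
                diffusion.transition_width,
                False, gmin, gspace, gshape, bias_v, bias_g,
                z_max, max_step, record_every, out_pos, out_v)
            if status == _kernels.DIVERGED:
                raise IntegrationError(f"divergent step at index {bad}")
            done += n
    else:
        grad = np.empty(d)
        for k in range(n_steps):
            t = k * dt
            g = -np.asarray(surface.gradient(s), float).reshape(d)
            g = g + np.asarray(bias(s.copy(), t), float).reshape(d)
            for j in range(d):
                dd, slope = _kernels.diffusion_at(
                    s[j], diffusion.form_code, diffusion.D_bulk,
                    diffusion.D_core, diffusion.transition_width)
                step = (thermo.beta * dd * g[j] + slope) * dt \
                    + np.sqrt(2.0 * dd * dt) * rng.standard_normal()
                if abs(step) > max_step:
                    raise IntegrationError(f"divergent step at index {k}")
                x = s[j] + step
                while x > z_max or x < -z_max:
                    x = 2.0 * z_max - x if x > z_max else -2.0 * z_max - x
                s[j] = x
            if (k + 1) % record_every == 0:
                out_pos[(k + 1) // record_every - 1] = s
                out_v[(k + 1) // record_every - 1] = 0.0

    stride = dt * record_every
    times = stride * np.arange(1, n_rec + 1)
    return CVTrajectory(times=times, values=out_pos, thermo=thermo,
                        stride=stride, seed=seed)
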