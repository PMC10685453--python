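"""Analytic model membrane free-energy landscapes.

The landscapes emulate the topography of drug-permeation potentials of
mean force: a flat bulk-water plateau at zero, a deep free-energy
minimum at each water/lipid interface, and a barrier at the membrane
core.  They are sums of Gaussian wells and barriers along projected
coordinates, so values and gradients are analytic everywhere — no grid
is involved in their evaluation.

One-dimensional surfaces live on the membrane-normal coordinate z (the
single permeation CV).  Two-dimensional surfaces live on the (ring, tail)
pair of membrane-normal distances of two drug moieties: the physical
profile acts on the midpoint m = (ring + tail)/2 while a smooth coupling
term penalises ring–tail separation, which keeps the minimum free energy
path on the diagonal by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .units import ThermoState

__all__ = [
    "ThermoState",
    "FeatureWidths",
    "ModelPotential",
    "DiffusionModel",
    "GaussianSurface",
    "make_membrane_potential",
    "make_protomer_pair",
]


@dataclass(frozen=True)
class FeatureWidths:
    """Gaussian widths (Å) of the landscape features."""

    well: float = 2.0
    barrier: float = 3.0
    coupling: float = 1.5

    def validate(self) -> None:
        for name in ("well", "barrier", "coupling"):
            if not getattr(self, name) > 0:
                raise ValueError(f"width {name!r} must be positive")


@dataclass(frozen=True)
class ModelPotential:
    """Parameters of the analytic membrane landscape.

    Energies in kJ·mol⁻¹, lengths in Å.  ``interfacial_min_depth`` is the
    depth of the interfacial minimum below the bulk level;
    ``core_barrier_height`` is the rise from that minimum to the membrane
    center.  ``tilt`` adds a linear perturbation tilt·z (z is the single
    CV in 1D, the ring/tail midpoint in 2D) and defaults to zero.
    """

    dimensionality: int = 1
    bulk_level: float = 0.0
    interfacial_min_depth: float = 40.0
    interfacial_min_position: float = 5.0
    core_barrier_height: float = 11.0
    widths: FeatureWidths = field(default_factory=FeatureWidths)
    coupling_strength: float = 25.0
    tilt: float = 0.0

    def validate(self) -> None:
        if self.dimensionality not in (1, 2):
            raise ValueError("dimensionality must be 1 or 2")
        self.widths.validate()
        if self.interfacial_min_depth < 0:
            raise ValueError("interfacial_min_depth must be >= 0")
        if self.core_barrier_height < 0:
            raise ValueError("core_barrier_height must be >= 0")
        if self.interfacial_min_position <= 0:
            raise ValueError("interfacial_min_position must be positive")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")


@dataclass(frozen=True)
class DiffusionModel:
    """Position-dependent diffusivity D(z) along the membrane normal.

    ``form`` is "constant" or "smooth-profile"; the smooth profile is a
    Gaussian dip from D_bulk to D_core of width ``transition_width``:
    D(z) = D_bulk + (D_core − D_bulk)·exp(−z²/2w²).  Symmetric and
    strictly positive for positive levels.
    """

    form: str = "constant"
    D_bulk: float = 0.5
    D_core: float = 0.5
    transition_width: float = 3.0

    def validate(self) -> None:
        if self.form not in ("constant", "smooth-profile"):
            raise ValueError(f"unknown diffusion form {self.form!r}")
        if not (self.D_bulk > 0 and self.D_core > 0):
            raise ValueError("diffusion levels must be positive")
        if not self.transition_width > 0:
            raise ValueError("transition_width must be positive")

    @property
    def form_code(self) -> int:
        return 0 if self.form == "constant" else 1

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        if self.form == "constant":
            return np.full_like(z, self.D_bulk)
        return self.D_bulk + (self.D_core - self.D_bulk) * np.exp(
            -0.5 * z * z / self.transition_width**2
        )


class GaussianSurface:
    """Analytic surface F(s) = const + Σ aᵢ·exp(−(pᵢ·s − cᵢ)²/2σᵢ²) + tilt·s + harmonics.

    Terms act on projected coordinates pᵢ·s, which expresses both on-axis
    features and ring–tail coupling in one closed form with exact
    gradients.  Optional per-coordinate harmonic terms implement
    umbrella-style restraints for diffusion-window runs.
    """

    def __init__(self, dimensionality, proj, centers, sigmas, amps,
                 const=0.0, tilt=None, harm_k=None, harm_center=None):
        self.dimensionality = int(dimensionality)
        d = self.dimensionality
        self.proj = np.atleast_2d(np.asarray(proj, dtype=float)).reshape(-1, d)
        self.centers = np.asarray(centers, dtype=float).ravel()
        self.sigmas = np.asarray(sigmas, dtype=float).ravel()
        self.amps = np.asarray(amps, dtype=float).ravel()
        if not (len(self.centers) == len(self.sigmas) == len(self.amps)
                == self.proj.shape[0]):
            raise ValueError("term arrays must have matching lengths")
        if np.any(self.sigmas <= 0):
            raise ValueError("term widths must be positive")
        self.const = float(const)
        self.tilt = np.zeros(d) if tilt is None else np.asarray(tilt, float).ravel()
        self.harm_k = np.zeros(d) if harm_k is None else np.asarray(harm_k, float).ravel()
        self.harm_center = (np.zeros(d) if harm_center is None
                            else np.asarray(harm_center, float).ravel())

    def _pts(self, s):
        s = np.asarray(s, dtype=float)
        d = self.dimensionality
        # "single" means one point was passed: scalar in 1D, a (d,) vector in 2D
        if d == 1:
            single = s.ndim == 0
            pts = s.reshape(-1, 1)
        else:
            single = s.ndim == 1
            pts = s.reshape(-1, d)
        return pts, single, s.shape

    def value(self, s):
        """F at point(s) s; accepts scalars/arrays (1D) or (d,)/(n, d) points (2D)."""
        pts, single, shape = self._pts(s)
        u = pts @ self.proj.T - self.centers          # (n, n_terms)
        v = self.const + (np.exp(-0.5 * (u / self.sigmas) ** 2) * self.amps).sum(axis=1)
        v = v + pts @ self.tilt
        v = v + 0.5 * ((pts - self.harm_center) ** 2 * self.harm_k).sum(axis=1)
        if single:
            return float(v[0])
        if self.dimensionality == 1:
            return v.reshape(shape)
        return v

    __call__ = value

    def gradient(self, s):
        """Exact analytic ∇F; same input conventions as :meth:`value`."""
        pts, single, shape = self._pts(s)
        u = pts @ self.proj.T - self.centers
        e = np.exp(-0.5 * (u / self.sigmas) ** 2) * self.amps
        coef = -e * u / self.sigmas**2                 # (n, n_terms)
        g = coef @ self.proj + self.tilt
        g = g + (pts - self.harm_center) * self.harm_k
        if single:
            return float(g[0, 0]) if self.dimensionality == 1 else g[0]
        if self.dimensionality == 1:
            return g[:, 0].reshape(shape)
        return g

    def plus_terms(self, proj, centers, sigmas, amps):
        """New surface with extra Gaussian terms appended."""
        proj = np.atleast_2d(np.asarray(proj, float)).reshape(-1, self.dimensionality)
        return GaussianSurface(
            self.dimensionality,
            np.vstack([self.proj, proj]),
            np.concatenate([self.centers, np.ravel(centers)]),
            np.concatenate([self.sigmas, np.ravel(sigmas)]),
            np.concatenate([self.amps, np.ravel(amps)]),
            const=self.const, tilt=self.tilt,
            harm_k=self.harm_k, harm_center=self.harm_center,
        )

    def with_restraint(self, k, center):
        """New surface with a harmonic restraint ½k(s−center)² per coordinate."""
        d = self.dimensionality
        k = np.broadcast_to(np.asarray(k, float), (d,))
        center = np.broadcast_to(np.asarray(center, float), (d,))
        out = GaussianSurface(d, self.proj, self.centers, self.sigmas, self.amps,
                              const=self.const, tilt=self.tilt,
                              harm_k=self.harm_k + k, harm_center=center)
        return out

    def with_tilt(self, tilt):
        out = GaussianSurface(self.dimensionality, self.proj, self.centers,
                              self.sigmas, self.amps, const=self.const,
                              tilt=tilt, harm_k=self.harm_k,
                              harm_center=self.harm_center)
        return out


def _calibrate_1d(depth, barrier, z0, sw, sb):
    """Solve well/barrier amplitudes so the constructed depth and core rise
    are met exactly despite Gaussian overlap.

    Returns (A, B, z_min): F(z) = −A[g(z−z0)+g(z+z0)] + B·g_b(z) with
    F(z_min) = −depth and F(0) = −depth + barrier, z_min the true minimum.
    """
    if depth == 0.0:
        return 0.0, barrier, z0

    def g(z, c, s):
        return np.exp(-0.5 * ((z - c) / s) ** 2)

    z_min = float(z0)
    A, B = depth, barrier
    for _ in range(200):
        # linear solve at the current minimum estimate
        a11 = -(g(z_min, z0, sw) + g(z_min, -z0, sw))
        a12 = g(z_min, 0.0, sb)
        a21 = -2.0 * g(0.0, z0, sw)
        a22 = 1.0
        rhs1 = -depth
        rhs2 = -depth + barrier
        det = a11 * a22 - a12 * a21
        A_new = (rhs1 * a22 - a12 * rhs2) / det
        B_new = (a11 * rhs2 - rhs1 * a21) / det
        # relocate the minimum by Newton on the analytic derivative
        z = z_min
        for _ in range(60):
            d1 = (-A_new * (-(z - z0) / sw**2 * g(z, z0, sw)
                            - (z + z0) / sw**2 * g(z, -z0, sw))
                  + B_new * (-z / sb**2) * g(z, 0.0, sb))
            d2_num = 1e-6
            d2 = ((-A_new * (-(z + d2_num - z0) / sw**2 * g(z + d2_num, z0, sw)
                             - (z + d2_num + z0) / sw**2 * g(z + d2_num, -z0, sw))
                   + B_new * (-(z + d2_num) / sb**2) * g(z + d2_num, 0.0, sb)) - d1) / d2_num
            if d2 <= 0:
                break
            z_new = z - d1 / d2
            if abs(z_new - z) < 1e-14:
                z = z_new
                break
            z = z_new
        converged = (abs(A_new - A) < 1e-13 * max(1.0, abs(A_new))
                     and abs(B_new - B) < 1e-13 * max(1.0, abs(B_new))
                     and abs(z - z_min) < 1e-13)
        A, B, z_min = A_new, B_new, z
        if converged:
            break
    return A, B, z_min


def make_membrane_potential(params: ModelPotential) -> GaussianSurface:
    """Build the analytic membrane landscape from its parameters.

    The well and barrier amplitudes are calibrated (small fixed-point
    solve) so that F(z_min) − F(bulk) = −interfacial_min_depth and
    F(0) − F(z_min) = +core_barrier_height hold exactly, not just in the
    non-overlapping limit.  The returned surface carries the calibrated
    minimum position in ``z_min``.
    """
    params.validate()
    w = params.widths
    A, B, z_min = _calibrate_1d(params.interfacial_min_depth,
                                params.core_barrier_height,
                                params.interfacial_min_position,
                                w.well, w.barrier)
    z0 = params.interfacial_min_position
    if params.dimensionality == 1:
        surf = GaussianSurface(
            1,
            proj=[[1.0], [1.0], [1.0]],
            centers=[z0, -z0, 0.0],
            sigmas=[w.well, w.well, w.barrier],
            amps=[-A, -A, B],
            const=params.bulk_level,
            tilt=[params.tilt],
        )
    else:
        C = params.coupling_strength
        half = [0.5, 0.5]
        surf = GaussianSurface(
            2,
            proj=[half, half, half, [1.0, -1.0]],
            centers=[z0, -z0, 0.0, 0.0],
            sigmas=[w.well, w.well, w.barrier, w.coupling],
            amps=[-A, -A, B, -C],
            const=params.bulk_level + C,
            tilt=[params.tilt / 2.0, params.tilt / 2.0],
        )
    surf.z_min = z_min
    surf.params = params
    return surf


def make_protomer_pair(base: ModelPotential, core_penalty: float,
                       penalty_width: float | None = None):
    """Neutral/charged landscape pair differing by a core-localised penalty.

    The charged surface equals the neutral one plus a Gaussian of height
    ``core_penalty`` centred at the membrane core (acting on the
    midpoint coordinate in 2D), emulating the destabilisation of the
    charged protomer inside the low-dielectric region.  The difference is
    exactly ``core_penalty`` at the core and decays to zero in bulk.
    """
    if core_penalty < 0:
        raise ValueError("core_penalty must be >= 0")
    neutral = make_membrane_potential(base)
    if core_penalty == 0.0:
        charged = make_membrane_potential(base)
        return neutral, charged
    pw = base.widths.barrier if penalty_width is None else float(penalty_width)
    if pw <= 0:
        raise ValueError("penalty_width must be positive")
    if base.dimensionality == 1:
        proj = [[1.0]]
    else:
        proj = [[0.5, 0.5]]
    charged = neutral.plus_terms(proj, [0.0], [pw], [core_penalty])
    charged.z_min = neutral.z_min
    charged.params = replace(base)
    return neutral, charged
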