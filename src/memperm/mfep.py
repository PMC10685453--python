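"""Minimum free energy paths on 2D surfaces by the string method.

A string of images is relaxed by steepest descent on the perpendicular
component of the interpolated gradient, with equal-arc-length
reparameterization after every update (the zero-temperature string
method).  The surface is interpolated bicubically; masked (unvisited)
bins are filled with a large penalty so paths cannot cross unsampled
territory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline, RectBivariateSpline
from scipy.optimize import minimize, minimize_scalar

from .fes import FreeEnergySurface

__all__ = ["StringPath", "PathError", "find_minima", "string_mfep",
           "profile_along_path"]

#: Energy offset added above the visited maximum when filling masked bins.
_MASK_PENALTY = 100.0


class PathError(RuntimeError):
    pass


@dataclass
class StringPath:
    """Ordered images in CV space with arc length and F along the path."""

    images: np.ndarray          # (n_images, d)
    arc_length: np.ndarray      # (n_images,), monotone from 0
    F_along: np.ndarray         # (n_images,)
    converged: bool
    iterations: int

    def reversed(self) -> "StringPath":
        arc = self.arc_length[-1] - self.arc_length[::-1]
        return StringPath(self.images[::-1].copy(), arc,
                          self.F_along[::-1].copy(), self.converged,
                          self.iterations)


def _filled(fes: FreeEnergySurface) -> np.ndarray:
    F = fes.F.copy()
    if np.any(fes.mask):
        fill = np.nanmax(F[fes.mask]) + _MASK_PENALTY
    else:
        raise PathError("surface has no visited bins")
    F[~fes.mask] = fill
    return F


def _spline(fes: FreeEnergySurface):
    if fes.dimensionality != 2:
        raise ValueError("string method requires a 2D surface")
    return RectBivariateSpline(fes.axes[0], fes.axes[1], _filled(fes),
                               kx=3, ky=3, s=0)


def _in_bounds(fes, pts):
    x, y = pts[..., 0], pts[..., 1]
    return ((x >= fes.axes[0][0]) & (x <= fes.axes[0][-1])
            & (y >= fes.axes[1][0]) & (y <= fes.axes[1][-1]))


def find_minima(fes: FreeEnergySurface, region=None):
    """Local minima of the surface, interpolation-refined, sorted by F.

    region is ((x_lo, x_hi), (y_lo, y_hi)) in 2D or (lo, hi) in 1D;
    None searches the whole surface.  Raises PathError when the region
    contains no visited bins or no local minimum.
    """
    if fes.dimensionality == 1:
        ax = fes.axes[0]
        lo, hi = (ax[0], ax[-1]) if region is None else region
        sel = fes.mask & (ax >= lo) & (ax <= hi)
        if not np.any(sel):
            raise PathError("no visited bins in region")
        F = np.where(fes.mask, fes.F, np.nanmax(fes.F[fes.mask]) + _MASK_PENALTY)
        interior = np.zeros_like(sel)
        interior[1:-1] = (F[1:-1] <= F[2:]) & (F[1:-1] <= F[:-2])
        cand = np.where(sel & interior)[0]
        if len(cand) == 0:
            raise PathError("no local minimum in region")
        spl = InterpolatedUnivariateSpline(ax, F, k=3)
        h = ax[1] - ax[0]
        out = []
        for i in cand:
            res = minimize_scalar(spl, bounds=(max(lo, ax[i] - h),
                                               min(hi, ax[i] + h)),
                                  method="bounded")
            out.append((float(res.fun), float(res.x)))
        out.sort()
        return np.array([[x] for _, x in out])

    spl = _spline(fes)
    F = _filled(fes)
    lo0, hi0 = (fes.axes[0][0], fes.axes[0][-1]) if region is None else region[0]
    lo1, hi1 = (fes.axes[1][0], fes.axes[1][-1]) if region is None else region[1]
    in_reg = (fes.axes[0][:, None] >= lo0) & (fes.axes[0][:, None] <= hi0) \
        & (fes.axes[1][None, :] >= lo1) & (fes.axes[1][None, :] <= hi1)
    if not np.any(fes.mask & in_reg):
        raise PathError("no visited bins in region")
    is_min = np.ones_like(F, bool)
    is_min[:-1] &= F[:-1] <= F[1:]
    is_min[1:] &= F[1:] <= F[:-1]
    is_min[:, :-1] &= F[:, :-1] <= F[:, 1:]
    is_min[:, 1:] &= F[:, 1:] <= F[:, :-1]
    is_min[[0, -1], :] = False
    is_min[:, [0, -1]] = False
    # demand a fully visited 3x3 neighbourhood: the interpolant rings next
    # to penalty-filled bins and would fabricate spurious minima there
    solid = np.ones_like(F, bool)
    solid[1:-1, 1:-1] = (fes.mask[:-2, :-2] & fes.mask[:-2, 1:-1]
                         & fes.mask[:-2, 2:] & fes.mask[1:-1, :-2]
                         & fes.mask[1:-1, 1:-1] & fes.mask[1:-1, 2:]
                         & fes.mask[2:, :-2] & fes.mask[2:, 1:-1]
                         & fes.mask[2:, 2:])
    cand = np.argwhere(is_min & fes.mask & solid & in_reg)
    if len(cand) == 0:
        raise PathError("no local minimum in region")
    h0, h1 = fes.spacing
    out = []
    for i, j in cand:
        x0 = np.array([fes.axes[0][i], fes.axes[1][j]])
        res = minimize(lambda p: float(spl.ev(p[0], p[1])), x0,
                       jac=lambda p: np.array([float(spl.ev(p[0], p[1], dx=1)),
                                               float(spl.ev(p[0], p[1], dy=1))]),
                       bounds=[(max(lo0, x0[0] - h0), min(hi0, x0[0] + h0)),
                               (max(lo1, x0[1] - h1), min(hi1, x0[1] + h1))],
                       method="L-BFGS-B")
        out.append((float(res.fun), tuple(res.x)))
    out.sort()
    # deduplicate refined positions that collapsed onto the same point
    uniq = []
    for fval, p in out:
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) > min(h0, h1) / 2
               for _, q in uniq):
            uniq.append((fval, p))
    return np.array([p for _, p in uniq])


def _reparameterize(images: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] == 0:
        return images
    targets = np.linspace(0.0, arc[-1], len(images))
    out = np.empty_like(images)
    for j in range(images.shape[1]):
        out[:, j] = np.interp(targets, arc, images[:, j])
    return out


def string_mfep(fes: FreeEnergySurface, start, end, n_images: int = 48,
                tol: float = 0.5, max_iter: int = 2000,
                waypoints=None) -> StringPath:
    """Minimum free energy path between two points on a 2D surface.

    Iterates steepest-descent moves of the interior images along the
    perpendicular gradient component, followed by equal-arc-length
    reparameterization; stops when the maximum perpendicular gradient
    falls below ``tol`` (kJ·mol⁻¹·Å⁻¹) or the images stop moving.
    The string is initialized as a straight line (through ``waypoints``
    if given).  Endpoints stay fixed.
    """
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    spl = _spline(fes)
    if np.allclose(start, end):
        f0 = float(spl.ev(start[0], start[1]))
        return StringPath(np.array([start]), np.array([0.0]),
                          np.array([f0]), True, 0)
    nodes = [start] + ([] if waypoints is None
                       else [np.asarray(w, float) for w in waypoints]) + [end]
    nodes = np.array(nodes)
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0, arc[-1], n_images)
    images = np.column_stack([np.interp(targets, arc, nodes[:, j])
                              for j in range(2)])
    if not np.all(_in_bounds(fes, images[[0, -1]])):
        raise PathError("endpoints outside the surface")

    ds = arc[-1] / (n_images - 1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gx = spl.ev(images[:, 0], images[:, 1], dx=1)
        gy = spl.ev(images[:, 0], images[:, 1], dy=1)
        g = np.column_stack([gx, gy])
        tan = np.empty_like(images)
        tan[1:-1] = images[2:] - images[:-2]
        tan[0] = images[1] - images[0]
        tan[-1] = images[-1] - images[-2]
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        gperp = g - (g * tan).sum(axis=1, keepdims=True) * tan
        gperp[[0, -1]] = 0.0
        maxg = float(np.abs(gperp).max())
        if maxg < tol:
            converged = True
            break
        # explicit-Euler step bounded by the local curvature (stability
        # requires h < 2/L with L the Hessian norm along the string)
        fxx = spl.ev(images[:, 0], images[:, 1], dx=2)
        fyy = spl.ev(images[:, 0], images[:, 1], dy=2)
        fxy = spl.ev(images[:, 0], images[:, 1], dx=1, dy=1)
        L = float(np.max(np.abs(fxx) + np.abs(fyy) + 2 * np.abs(fxy)))
        h = 1.0 / max(L, maxg / (0.3 * ds), 1e-12)
        step = -h * gperp
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        cap = 0.3 * ds
        scale = np.where(norm > cap, cap / np.maximum(norm, 1e-300), 1.0)
        new = images + step * scale
        new[[0, -1]] = images[[0, -1]]
        inb = _in_bounds(fes, new)
        if not np.all(inb):
            raise PathError(f"image {int(np.argmin(inb))} left the surface")
        images = _reparameterize(new)

    seg = np.linalg.norm(np.diff(images, axis=0), axis=1)
    arc_length = np.concatenate([[0.0], np.cumsum(seg)])
    F_along = spl.ev(images[:, 0], images[:, 1])
    # a converged path must not rest on penalty-filled (unsampled) bins
    idx = [np.clip(np.round((images[:, j] - fes.axes[j][0]) / fes.spacing[j])
                   .astype(int), 0, len(fes.axes[j]) - 1) for j in range(2)]
    if np.any(~fes.mask[idx[0], idx[1]]):
        bad = int(np.argmax(~fes.mask[idx[0], idx[1]]))
        raise PathError(f"image {bad} lies in an unvisited region")
    return StringPath(images, arc_length, np.asarray(F_along), converged, it)


def profile_along_path(fes: FreeEnergySurface, path: StringPath,
                       bulk_end: str = "mean"):
    """1D free-energy profile along a converged path.

    Returns (arc_length, F) with F re-referenced so the bulk endpoint is
    zero: ``bulk_end`` is "first", "last", or "mean" (average of both
    endpoints, appropriate when both ends sit in bulk water).
    """
    F = path.F_along.copy()
    if bulk_end == "first":
        F -= F[0]
    elif bulk_end == "last":
        F -= F[-1]
    elif bulk_end == "mean":
        F -= 0.5 * (F[0] + F[-1])
    else:
        raise ValueError(f"unknown bulk_end {bulk_end!r}")
    return path.arc_length.copy(), F
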