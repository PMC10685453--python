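"""Numba-compiled numerical cores.

Everything here works on plain arrays so it can be jitted: analytic
Gaussian-sum surfaces are passed as term arrays, metadynamics bias as
flat grids with (min, spacing, shape) descriptors.  Grids are row-major;
d is 1 or 2 throughout.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Status codes returned by integrate_chunk.
OK = 0
DIVERGED = 1


@njit(cache=True)
def surface_value(s, proj, centers, sigmas, amps, const, tiltv, harm_k, harm_c):
    """F at point s (shape (d,)) for a Gaussian-sum + tilt + harmonic surface."""
    d = s.shape[0]
    v = const
    for t in range(amps.shape[0]):
        u = -centers[t]
        for j in range(d):
            u += proj[t, j] * s[j]
        v += amps[t] * math.exp(-0.5 * u * u / (sigmas[t] * sigmas[t]))
    for j in range(d):
        v += tiltv[j] * s[j]
        dz = s[j] - harm_c[j]
        v += 0.5 * harm_k[j] * dz * dz
    return v


@njit(cache=True)
def surface_grad(s, grad_out, proj, centers, sigmas, amps, tiltv, harm_k, harm_c):
    """Analytic gradient of the surface at s, written into grad_out (d,)."""
    d = s.shape[0]
    for j in range(d):
        grad_out[j] = tiltv[j] + harm_k[j] * (s[j] - harm_c[j])
    for t in range(amps.shape[0]):
        u = -centers[t]
        for j in range(d):
            u += proj[t, j] * s[j]
        inv2 = 1.0 / (sigmas[t] * sigmas[t])
        e = amps[t] * math.exp(-0.5 * u * u * inv2)
        coef = -e * u * inv2
        for j in range(d):
            grad_out[j] += coef * proj[t, j]


@njit(cache=True)
def diffusion_at(z, dform, d_bulk, d_core, tw):
    """(D, dD/dz) at coordinate z.  dform 0: constant; 1: smooth Gaussian core."""
    if dform == 0:
        return d_bulk, 0.0
    e = math.exp(-0.5 * z * z / (tw * tw))
    dd = d_bulk + (d_core - d_bulk) * e
    slope = (d_core - d_bulk) * e * (-z / (tw * tw))
    return dd, slope


@njit(cache=True)
def grid_interp(s, gmin, gspace, gshape, flat):
    """Multilinear interpolation of a flat row-major grid at point s (d=1 or 2)."""
    d = gmin.shape[0]
    if d == 1:
        x = (s[0] - gmin[0]) / gspace[0]
        i = int(math.floor(x))
        if i < 0:
            i = 0
        if i > gshape[0] - 2:
            i = gshape[0] - 2
        f = x - i
        if f < 0.0:
            f = 0.0
        if f > 1.0:
            f = 1.0
        return flat[i] * (1.0 - f) + flat[i + 1] * f
    x0 = (s[0] - gmin[0]) / gspace[0]
    x1 = (s[1] - gmin[1]) / gspace[1]
    i0 = int(math.floor(x0))
    i1 = int(math.floor(x1))
    if i0 < 0:
        i0 = 0
    if i0 > gshape[0] - 2:
        i0 = gshape[0] - 2
    if i1 < 0:
        i1 = 0
    if i1 > gshape[1] - 2:
        i1 = gshape[1] - 2
    f0 = min(max(x0 - i0, 0.0), 1.0)
    f1 = min(max(x1 - i1, 0.0), 1.0)
    n1 = gshape[1]
    v00 = flat[i0 * n1 + i1]
    v01 = flat[i0 * n1 + i1 + 1]
    v10 = flat[(i0 + 1) * n1 + i1]
    v11 = flat[(i0 + 1) * n1 + i1 + 1]
    return (v00 * (1 - f0) * (1 - f1) + v01 * (1 - f0) * f1
            + v10 * f0 * (1 - f1) + v11 * f0 * f1)


@njit(cache=True)
def grid_interp_many(pts, gmin, gspace, gshape, flat, out):
    for k in range(pts.shape[0]):
        out[k] = grid_interp(pts[k], gmin, gspace, gshape, flat)


@njit(cache=True)
def integrate_chunk(s, step0, n_steps, dt, beta, noise,
                    proj, centers, sigmas, amps, tiltv, harm_k, harm_c,
                    dform, d_bulk, d_core, tw,
                    has_bias, gmin, gspace, gshape, bias_v, bias_g,
                    z_max, max_step, rec_every, out_pos, out_v):
    """Euler–Maruyama overdamped Langevin chunk under a frozen bias grid.

    Itô convention with the spurious drift dD/dz included.  Reflective
    boundaries at ±z_max per coordinate.  Records every rec_every-th step
    (global step counting) into out_pos/out_v rows (global_step+1)//rec_every-1.
    Returns (status, bad_step).
    """
    d = s.shape[0]
    grad = np.empty(d)
    for k in range(n_steps):
        surface_grad(s, grad, proj, centers, sigmas, amps, tiltv, harm_k, harm_c)
        if has_bias:
            for j in range(d):
                gslice = bias_g[j]
                grad[j] += grid_interp(s, gmin, gspace, gshape, gslice)
        for j in range(d):
            dd, slope = diffusion_at(s[j], dform, d_bulk, d_core, tw)
            step = (-beta * dd * grad[j] + slope) * dt \
                + math.sqrt(2.0 * dd * dt) * noise[k, j]
            if abs(step) > max_step:
                return DIVERGED, step0 + k
            x = s[j] + step
            # reflective boundaries
            while x > z_max or x < -z_max:
                if x > z_max:
                    x = 2.0 * z_max - x
                else:
                    x = -2.0 * z_max - x
            s[j] = x
        gstep = step0 + k + 1
        if gstep % rec_every == 0:
            row = gstep // rec_every - 1
            for j in range(d):
                out_pos[row, j] = s[j]
            if has_bias:
                out_v[row] = grid_interp(s, gmin, gspace, gshape, bias_v[0])
            else:
                out_v[row] = 0.0
    return OK, -1


@njit(cache=True)
def deposit_kernel(center, sigma, height, cutoff,
                   gmin, gspace, gshape, bias_v, bias_g):
    """Accumulate one Gaussian kernel (and its analytic gradient) on the grids.

    bias_v has shape (1, n_flat); bias_g has shape (d, n_flat).
    The kernel is truncated at ``cutoff`` sigmas per dimension.
    """
    d = center.shape[0]
    if d == 1:
        lo = int(math.ceil((center[0] - cutoff * sigma[0] - gmin[0]) / gspace[0]))
        hi = int(math.floor((center[0] + cutoff * sigma[0] - gmin[0]) / gspace[0]))
        if lo < 0:
            lo = 0
        if hi > gshape[0] - 1:
            hi = gshape[0] - 1
        inv2 = 1.0 / (sigma[0] * sigma[0])
        for i in range(lo, hi + 1):
            dz = gmin[0] + i * gspace[0] - center[0]
            e = height * math.exp(-0.5 * dz * dz * inv2)
            bias_v[0, i] += e
            bias_g[0, i] += -e * dz * inv2
    else:
        lo0 = int(math.ceil((center[0] - cutoff * sigma[0] - gmin[0]) / gspace[0]))
        hi0 = int(math.floor((center[0] + cutoff * sigma[0] - gmin[0]) / gspace[0]))
        lo1 = int(math.ceil((center[1] - cutoff * sigma[1] - gmin[1]) / gspace[1]))
        hi1 = int(math.floor((center[1] + cutoff * sigma[1] - gmin[1]) / gspace[1]))
        if lo0 < 0:
            lo0 = 0
        if hi0 > gshape[0] - 1:
            hi0 = gshape[0] - 1
        if lo1 < 0:
            lo1 = 0
        if hi1 > gshape[1] - 1:
            hi1 = gshape[1] - 1
        inv20 = 1.0 / (sigma[0] * sigma[0])
        inv21 = 1.0 / (sigma[1] * sigma[1])
        n1 = gshape[1]
        for i0 in range(lo0, hi0 + 1):
            dz0 = gmin[0] + i0 * gspace[0] - center[0]
            e0 = math.exp(-0.5 * dz0 * dz0 * inv20)
            for i1 in range(lo1, hi1 + 1):
                dz1 = gmin[1] + i1 * gspace[1] - center[1]
                e = height * e0 * math.exp(-0.5 * dz1 * dz1 * inv21)
                idx = i0 * n1 + i1
                bias_v[0, idx] += e
                bias_g[0, idx] += -e * dz0 * inv20
                bias_g[1, idx] += -e * dz1 * inv21


@njit(cache=True)
def c_from_bias_grid(bias_flat, gshape, gamma, beta):
    """Tiwary–Parrinello reweighting offset c from the current bias grid.

    c = (1/beta) * ln[ ∫ exp(gamma/(gamma-1) beta V) / ∫ exp(1/(gamma-1) beta V) ]
    by trapezoidal quadrature on the grid (half weights at the boundary
    nodes), log-sum-exp guarded; the grid spacing cancels in the ratio.
    """
    a1 = gamma / (gamma - 1.0) * beta
    a2 = beta / (gamma - 1.0)
    n = bias_flat.shape[0]
    m = bias_flat[0]
    for i in range(n):
        if bias_flat[i] > m:
            m = bias_flat[i]
    d = gshape.shape[0]
    n1 = gshape[1] if d == 2 else 1
    s1 = 0.0
    s2 = 0.0
    for i in range(n):
        w = 1.0
        if d == 1:
            if i == 0 or i == n - 1:
                w *= 0.5
        else:
            i0 = i // n1
            i1 = i % n1
            if i0 == 0 or i0 == gshape[0] - 1:
                w *= 0.5
            if i1 == 0 or i1 == n1 - 1:
                w *= 0.5
        dv = bias_flat[i] - m
        s1 += w * math.exp(a1 * dv)
        s2 += w * math.exp(a2 * dv)
    return ((a1 - a2) * m + math.log(s1) - math.log(s2)) / beta


@njit(cache=True)
def kernel_sum_at(s, kcenters, ksigmas, kheights, n_kernels, cutoff):
    """Exact bias V(s) as a truncated sum over the first n_kernels kernels."""
    d = s.shape[0]
    tot = 0.0
    for k in range(n_kernels):
        arg = 0.0
        skip = False
        for j in range(d):
            u = (s[j] - kcenters[k, j]) / ksigmas[k, j]
            if abs(u) > cutoff:
                skip = True
                break
            arg += u * u
        if not skip:
            tot += kheights[k] * math.exp(-0.5 * arg)
    return tot
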