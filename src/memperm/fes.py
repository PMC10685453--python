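"""Free-energy-surface reconstruction from biased CV trajectories.

Frames are reweighted with w = exp(β(V(s,t) − c(t))), histogrammed, and
converted to F = −kT·ln(weighted density).  Errors come from block
averaging (three contiguous blocks by default), profiles are symmetrized
in probability space, and an independent bias-based estimate
F = −γ/(γ−1)·V(s, t_end) serves as a cross-check of the reweighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import CVTrajectory
from .metad import (BiasGrid, HillsLedger, ReweightState, evaluate_bias,
                    replay_bias_at_frames)
from .units import ThermoState

__all__ = ["FreeEnergySurface", "reweight_to_fes", "block_error",
           "symmetrize", "asymmetry", "bias_based_fes", "marginal_z",
           "EstimationError"]


class EstimationError(RuntimeError):
    pass


@dataclass
class FreeEnergySurface:
    """Gridded F over 1 or 2 CV axes with per-bin errors and a mask.

    axes hold bin centers (uniform, ascending).  mask is True on visited
    bins; unvisited bins hold np.nan in F and are never imputed.
    reference is "min-zero" (min over visited bins = 0) or "bulk-zero"
    (mean over the bulk region = 0, bulk meaning |z| >= bulk_cut on the
    membrane-normal coordinate — the single CV in 1D, the ring/tail
    midpoint in 2D).
    """

    axes: tuple
    F: np.ndarray
    error: np.ndarray
    mask: np.ndarray
    reference: str
    thermo: ThermoState
    bulk_cut: float | None = None
    labels: tuple = None

    def __post_init__(self):
        self.axes = tuple(np.asarray(a, float) for a in self.axes)
        self.F = np.asarray(self.F, float)
        self.error = np.asarray(self.error, float)
        self.mask = np.asarray(self.mask, bool)
        shape = tuple(len(a) for a in self.axes)
        if self.F.shape != shape or self.mask.shape != shape \
                or self.error.shape != shape:
            raise ValueError("F/error/mask shapes must match the axes")
        if self.reference not in ("min-zero", "bulk-zero", "none"):
            raise ValueError(f"unknown reference {self.reference!r}")
        with np.errstate(invalid="ignore"):
            if np.any(self.error[self.mask & np.isfinite(self.error)] < 0):
                raise ValueError("errors must be non-negative")
        if self.labels is None:
            self.labels = ("cv_cq",) if self.dimensionality == 1 else (
                "cv_ring", "cv_tail")

    @property
    def dimensionality(self) -> int:
        return len(self.axes)

    @property
    def spacing(self) -> np.ndarray:
        return np.array([a[1] - a[0] for a in self.axes])

    def copy(self) -> "FreeEnergySurface":
        return FreeEnergySurface(tuple(a.copy() for a in self.axes),
                                 self.F.copy(), self.error.copy(),
                                 self.mask.copy(), self.reference,
                                 self.thermo, self.bulk_cut, self.labels)

    def z_of_bins(self) -> np.ndarray:
        """Membrane-normal coordinate of each bin (midpoint of the CVs in 2D)."""
        if self.dimensionality == 1:
            return self.axes[0]
        return 0.5 * (self.axes[0][:, None] + self.axes[1][None, :])

    def bulk_mask(self, bulk_cut: float | None = None) -> np.ndarray:
        """Visited bins representing the solvated state.

        |z| ≥ bulk_cut; in 2D additionally restricted to the diagonal
        (ring ≈ tail) band, since bins with separated moieties carry the
        coupling penalty and do not represent bulk water.
        """
        cut = self.bulk_cut if bulk_cut is None else bulk_cut
        if cut is None:
            raise ValueError("no bulk_cut defined for bulk referencing")
        sel = self.mask & (np.abs(self.z_of_bins()) >= cut)
        if self.dimensionality == 2 and np.any(sel):
            v = np.abs(self.axes[0][:, None] - self.axes[1][None, :])
            tol = float(min(self.spacing)) / 4.0
            vmin = v[sel].min()
            sel = sel & (v <= vmin + tol)
        return sel

    def re_reference(self, reference: str,
                     bulk_cut: float | None = None) -> "FreeEnergySurface":
        """Shift F to the requested reference convention (returns a copy)."""
        out = self.copy()
        if not np.any(out.mask):
            raise EstimationError("all bins are masked; run longer")
        if reference == "min-zero":
            out.F = out.F - np.nanmin(out.F[out.mask])
        elif reference == "bulk-zero":
            bm = out.bulk_mask(bulk_cut)
            if not np.any(bm):
                raise EstimationError("no visited bins in the bulk region")
            out.F = out.F - np.nanmean(out.F[bm])
            if bulk_cut is not None:
                out.bulk_cut = bulk_cut
        elif reference != "none":
            raise ValueError(f"unknown reference {reference!r}")
        out.reference = reference
        return out


def _default_axes(traj_values, bins, cv_range, bin_width=0.5):
    d = traj_values.shape[1]
    if cv_range is None:
        lim = np.ceil(np.abs(traj_values).max() / bin_width) * bin_width
        cv_range = [(-lim, lim)] * d
    elif np.isscalar(cv_range):
        cv_range = [(-float(cv_range), float(cv_range))] * d
    else:
        cv_range = [tuple(r) for r in np.atleast_2d(np.asarray(cv_range, float))]
        if len(cv_range) == 1:
            cv_range = cv_range * d
    if bins is None:
        bins = [int(round((hi - lo) / bin_width)) for lo, hi in cv_range]
    elif np.isscalar(bins):
        bins = [int(bins)] * d
    else:
        bins = [int(b) for b in bins]
    edges = [np.linspace(lo, hi, nb + 1) for (lo, hi), nb in zip(cv_range, bins)]
    return edges


def _frame_weights(traj: CVTrajectory, ledger: HillsLedger | None,
                   rwstate: ReweightState | None, bias_grid: BiasGrid | None):
    """log-weights β(V − c) per frame; zero for unbiased trajectories."""
    beta = traj.thermo.beta
    if ledger is None or len(ledger) == 0:
        return np.zeros(traj.n_frames)
    if traj.v_bias is not None:
        v = traj.v_bias
    else:
        if bias_grid is None:
            lim = float(np.ceil(np.abs(traj.values).max() + 1.0))
            sp = float(ledger.sigmas[: len(ledger)].min()) / 5.0
            bias_grid = BiasGrid.from_spacing(
                np.full(traj.dimensionality, -lim),
                np.full(traj.dimensionality, lim), sp)
        v = replay_bias_at_frames(traj, ledger, bias_grid)
    if rwstate is None or rwstate.times.size == 0:
        raise ValueError("reweight state required for a biased trajectory")
    c = rwstate.c_at(traj.times)
    return beta * (v - c)


def _weighted_fes(values, log_w, edges, thermo, reference, bulk_cut, labels):
    lw = log_w - log_w.max() if len(log_w) else log_w
    hist, _ = np.histogramdd(values, bins=edges, weights=np.exp(lw))
    mask = hist > 0
    if not np.any(mask):
        raise EstimationError("no frames fell inside the histogram range; "
                              "run longer or widen the range")
    F = np.full(hist.shape, np.nan)
    F[mask] = -thermo.kT * np.log(hist[mask])
    axes = tuple(0.5 * (e[1:] + e[:-1]) for e in edges)
    fes = FreeEnergySurface(axes, F, np.zeros_like(F), mask, "none", thermo,
                            bulk_cut, labels)
    return fes.re_reference(reference, bulk_cut)


def reweight_to_fes(traj: CVTrajectory, ledger: HillsLedger | None,
                    rwstate: ReweightState | None = None,
                    burn_in: float = 1.0 / 9.0, bins=None, cv_range=None,
                    bias_grid: BiasGrid | None = None,
                    reference: str = "min-zero",
                    bulk_cut: float | None = None) -> FreeEnergySurface:
    """Reweighted free energy surface from a (possibly biased) trajectory.

    burn_in is the fraction of frames discarded from the start (default
    1/9, mirroring 500 ns discarded of 4.5 μs).  For an unbiased run
    (empty ledger) all weights are equal and the result reduces to
    −kT·ln(histogram).
    """
    if not 0 <= burn_in < 1:
        raise ValueError("burn_in must be in [0, 1)")
    log_w = _frame_weights(traj, ledger, rwstate, bias_grid)
    i0 = int(np.floor(burn_in * traj.n_frames))
    values, log_w = traj.values[i0:], log_w[i0:]
    edges = _default_axes(traj.values, bins, cv_range)
    n_bins_total = int(np.prod([len(e) - 1 for e in edges]))
    if len(values) < 10 * n_bins_total:
        raise EstimationError(
            f"only {len(values)} post-burn-in frames for {n_bins_total} bins; "
            "need at least 10 frames per bin")
    return _weighted_fes(values, log_w, edges, traj.thermo, reference,
                         bulk_cut, traj.labels)


def block_error(traj: CVTrajectory, ledger: HillsLedger | None,
                rwstate: ReweightState | None = None, n_blocks: int = 3,
                burn_in: float = 1.0 / 9.0, bins=None, cv_range=None,
                bias_grid: BiasGrid | None = None,
                reference: str = "min-zero",
                bulk_cut: float | None = None) -> FreeEnergySurface:
    """FES with per-bin standard errors from contiguous block averaging.

    The post-burn-in data are cut into ``n_blocks`` equal time slices;
    each block FES is re-referenced by its mean offset against the
    full-data estimate on commonly visited bins before the spread is
    taken.  Bins missing from any block get a NaN (masked) error.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    log_w = _frame_weights(traj, ledger, rwstate, bias_grid)
    i0 = int(np.floor(burn_in * traj.n_frames))
    values, log_w = traj.values[i0:], log_w[i0:]
    if len(values) < n_blocks:
        raise ValueError("fewer post-burn-in frames than blocks")
    edges = _default_axes(traj.values, bins, cv_range)
    full = _weighted_fes(values, log_w, edges, traj.thermo, reference,
                         bulk_cut, traj.labels)
    bounds = np.linspace(0, len(values), n_blocks + 1).astype(int)
    block_F = []
    common = full.mask.copy()
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        try:
            bf = _weighted_fes(values[sl], log_w[sl], edges, traj.thermo,
                               "none", bulk_cut, traj.labels)
        except EstimationError:
            raise EstimationError("a block has no visited bins; run longer")
        block_F.append(bf)
        common &= bf.mask
    if not np.any(common):
        raise EstimationError("no bin visited in every block")
    stacked = np.full((n_blocks,) + full.F.shape, np.nan)
    for b, bf in enumerate(block_F):
        offset = np.nanmean(bf.F[common] - full.F[common])
        stacked[b][bf.mask] = bf.F[bf.mask] - offset
    error = np.full(full.F.shape, np.nan)
    error[common] = np.std(stacked[:, common], axis=0, ddof=1) / np.sqrt(n_blocks)
    out = full.copy()
    out.error = error
    return out


def _flip(arr):
    return arr[tuple(slice(None, None, -1) for _ in range(arr.ndim))]


def _check_symmetric_axes(fes: FreeEnergySurface):
    for a in fes.axes:
        if not np.allclose(a, -a[::-1], atol=1e-9):
            raise ValueError("axes must be symmetric about zero to symmetrize")


def symmetrize(fes: FreeEnergySurface) -> FreeEnergySurface:
    """Mirror-symmetrized surface, averaged in probability space.

    F_sym(s) = −kT·ln[(e^{−βF(s)} + e^{−βF(−s)})/2]; in 2D the mirror is
    s → −s on both axes simultaneously (the bilayer inversion).  Where
    only one of a mirror pair is visited, its value is copied to both
    (the missing mirror image carries no statistics of its own).
    Idempotent.
    """
    _check_symmetric_axes(fes)
    beta = fes.thermo.beta
    F, Fr = fes.F, _flip(fes.F)
    m, mr = fes.mask, _flip(fes.mask)
    both = m & mr
    out = fes.copy()
    out.F = np.full(F.shape, np.nan)
    with np.errstate(invalid="ignore", over="ignore"):
        out.F[both] = -(1.0 / beta) * (
            np.logaddexp(-beta * F[both], -beta * Fr[both]) - np.log(2.0))
    only = m & ~mr
    out.F[only] = F[only]
    onlyr = mr & ~m
    out.F[onlyr] = Fr[onlyr]
    out.mask = m | mr
    err, errr = fes.error, _flip(fes.error)
    out.error = np.full(F.shape, np.nan)
    with np.errstate(invalid="ignore"):
        out.error[both] = 0.5 * np.sqrt(err[both] ** 2 + errr[both] ** 2)
    out.error[only] = err[only]
    out.error[onlyr] = errr[onlyr]
    return out


def asymmetry(fes: FreeEnergySurface) -> float:
    """Max |F(s) − F(−s)| over mirror pairs visited on both sides."""
    _check_symmetric_axes(fes)
    both = fes.mask & _flip(fes.mask)
    if not np.any(both):
        return np.nan
    return float(np.nanmax(np.abs(fes.F - _flip(fes.F))[both]))


def bias_based_fes(ledger: HillsLedger, grid: BiasGrid,
                   reference: str = "min-zero",
                   bulk_cut: float | None = None) -> FreeEnergySurface:
    """Cross-estimator from the final bias: F = −γ/(γ−1)·V(s, t_end) + const.

    Used to validate the reweighted estimate; exact only in the
    long-time well-tempered limit.
    """
    t_end = float(ledger.times[len(ledger) - 1]) if len(ledger) else 0.0
    vgrid = evaluate_bias(ledger, grid, t_end)
    g = ledger.bias_factor
    F = -(g / (g - 1.0)) * vgrid.values
    axes = tuple(grid.axis(j) for j in range(grid.dimensionality))
    mask = np.ones(F.shape, bool)
    fes = FreeEnergySurface(axes, F, np.zeros_like(F), mask, "none",
                            ledger.thermo, bulk_cut)
    return fes.re_reference(reference, bulk_cut)


def marginal_z(fes: FreeEnergySurface, bin_width: float | None = None,
               reference: str = "bulk-zero",
               bulk_cut: float | None = None) -> FreeEnergySurface:
    """Project a 2D (ring, tail) surface onto the membrane normal z.

    z is the moiety midpoint (ring + tail)/2; the projection is the
    Boltzmann marginal F(z) = −kT·ln Σ_bins e^{−βF(a,b)} over bins with
    midpoint in each z slab.  A 1D surface is returned unchanged (up to
    re-referencing).
    """
    if fes.dimensionality == 1:
        return fes.re_reference(reference, bulk_cut)
    beta = fes.thermo.beta
    h = float(fes.spacing[0])
    w = h if bin_width is None else float(bin_width)
    z = fes.z_of_bins()
    lim = np.ceil((np.abs(z).max() + w / 2) / w) * w
    edges = np.arange(-lim, lim + w / 2, w)
    centers = 0.5 * (edges[1:] + edges[:-1])
    zv = z[fes.mask]
    Fv = fes.F[fes.mask]
    idx = np.clip(np.digitize(zv, edges) - 1, 0, len(centers) - 1)
    shift = Fv.min()
    pop = np.zeros(len(centers))
    np.add.at(pop, idx, np.exp(-beta * (Fv - shift)))
    mask = pop > 0
    F1 = np.full(len(centers), np.nan)
    F1[mask] = -fes.thermo.kT * np.log(pop[mask]) + shift
    out = FreeEnergySurface((centers,), F1, np.zeros_like(F1), mask, "none",
                            fes.thermo, bulk_cut if bulk_cut is not None
                            else fes.bulk_cut, ("z",))
    return out.re_reference(reference, bulk_cut)
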