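"""Protonation-state coupling of permeation free energy surfaces.

The neutral and protonated protomer surfaces, each bulk-referenced, are
combined into the protonation-dependent surface.  The neutral surface
is first raised by the aqueous acid–base shift kT·ln10·(pKa − pH) so
that bulk populations reproduce the Henderson–Hasselbalch ratio; the
combined surface is then the exact partition-function (log-sum-exp)
mixture

    F_comb(s) = −kT · ln( e^{−βF₀'(s)} + e^{−βF₊(s)} ),

which equals the population-weighted average of the two surfaces minus
the mixing-entropy term.  Proton-transfer kinetics are not modelled;
the zero-crossings of the difference map mark where the preferred
protomer flips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fes import FreeEnergySurface
from .units import ThermoState

__all__ = ["ProtomerSpec", "aqueous_shift", "shift_surface", "populations",
           "combine_surfaces", "delta_surface"]


@dataclass(frozen=True)
class ProtomerSpec:
    """Acid–base context for a protomer pair (defaults: chloroquine-like).

    pKa defaults to 10.4 (the second, amine protonation at 310 K) and pH
    to 7; pKa1 = 8.1 is carried for reference although only the
    neutral/monoprotonated pair is combined.
    """

    label: str = "CQ"
    charge: int = 1
    pKa: float = 10.4
    pH: float = 7.0
    thermo: ThermoState = field(default_factory=ThermoState)
    pKa1: float = 8.1

    def __post_init__(self):
        if not (math.isfinite(self.pKa) and math.isfinite(self.pH)):
            raise ValueError("pKa and pH must be finite")


def aqueous_shift(pKa: float, pH: float, thermo: ThermoState) -> float:
    """Free-energy shift kT·ln10·(pKa − pH) of the neutral protomer (kJ·mol⁻¹).

    Positive when the protonated form dominates in bulk water (pH < pKa);
    the neutral surface is raised by this amount before combination.
    Antisymmetric under pKa ↔ pH.
    """
    return thermo.kT * math.log(10.0) * (pKa - pH)


def _check_pair(fa: FreeEnergySurface, fb: FreeEnergySurface):
    if fa.dimensionality != fb.dimensionality:
        raise ValueError("surfaces have different dimensionality")
    for a, b in zip(fa.axes, fb.axes):
        if len(a) != len(b) or not np.allclose(a, b, atol=1e-9):
            raise ValueError("surfaces must share axes")


def shift_surface(fes: FreeEnergySurface, shift: float) -> FreeEnergySurface:
    """Surface with a constant added to F (reference left as 'none')."""
    out = fes.copy()
    out.F = out.F + shift
    out.reference = "none"
    return out


def populations(F_neutral_shifted: FreeEnergySurface,
                F_protonated: FreeEnergySurface):
    """Per-bin protomer fractions (p_neutral, p_protonated).

    Inputs must share axes and a common (bulk) reference, with the
    aqueous shift already applied to the neutral surface.  p₀ + p₊ = 1
    on every unmasked bin; bins masked in either input are NaN.
    """
    _check_pair(F_neutral_shifted, F_protonated)
    beta = F_neutral_shifted.thermo.beta
    d = F_protonated.F - F_neutral_shifted.F     # F₊ − F₀'
    both = F_neutral_shifted.mask & F_protonated.mask
    # p₀ = e^{−βF₀'} / (e^{−βF₀'} + e^{−βF₊}) = 1/(1 + e^{−βd}); the
    # logistic form underflows gracefully and the complementary fraction
    # uses the opposite sign so the pair sums to 1 exactly
    p0 = np.full(d.shape, np.nan)
    pp = np.full(d.shape, np.nan)
    with np.errstate(over="ignore", invalid="ignore"):
        p0[both] = 1.0 / (1.0 + np.exp(-beta * d[both]))
        pp[both] = 1.0 / (1.0 + np.exp(beta * d[both]))
    return p0, pp


def combine_surfaces(F_neutral_shifted: FreeEnergySurface,
                     F_protonated: FreeEnergySurface,
                     reference: str = "bulk-zero",
                     bulk_cut: float | None = None) -> FreeEnergySurface:
    """Protonation-dependent surface: log-sum-exp mixture of the protomers.

    Satisfies min(F₀', F₊) − kT·ln2 ≤ F_comb ≤ min(F₀', F₊) bin-wise and
    −kT·ln pᵢ = Fᵢ − F_comb exactly.  Errors are combined
    population-weighted in quadrature.  Re-referenced to bulk by default
    (pass reference="none" to keep the raw mixture for identity checks).
    """
    _check_pair(F_neutral_shifted, F_protonated)
    beta = F_neutral_shifted.thermo.beta
    kT = F_neutral_shifted.thermo.kT
    both = F_neutral_shifted.mask & F_protonated.mask
    F = np.full(F_protonated.F.shape, np.nan)
    with np.errstate(invalid="ignore"):
        F[both] = -kT * np.logaddexp(-beta * F_neutral_shifted.F[both],
                                     -beta * F_protonated.F[both])
    p0, pp = populations(F_neutral_shifted, F_protonated)
    err = np.full(F.shape, np.nan)
    with np.errstate(invalid="ignore"):
        err[both] = np.sqrt(
            (p0[both] * F_neutral_shifted.error[both]) ** 2
            + (pp[both] * F_protonated.error[both]) ** 2)
    bulk_cut = bulk_cut if bulk_cut is not None else F_protonated.bulk_cut
    out = FreeEnergySurface(F_protonated.axes, F, err, both, "none",
                            F_protonated.thermo, bulk_cut,
                            F_protonated.labels)
    if reference != "none":
        out = out.re_reference(reference, bulk_cut)
    return out


def delta_surface(F_protonated: FreeEnergySurface,
                  F_neutral_shifted: FreeEnergySurface) -> FreeEnergySurface:
    """Difference map ΔF = F₊ − F₀' (negative where protonation is preferred).

    In bulk water ΔF → −aqueous_shift(pKa, pH) by construction; its
    zero-crossing band marks the most likely proton-transfer locations.
    """
    _check_pair(F_protonated, F_neutral_shifted)
    both = F_protonated.mask & F_neutral_shifted.mask
    dF = np.full(F_protonated.F.shape, np.nan)
    dF[both] = F_protonated.F[both] - F_neutral_shifted.F[both]
    with np.errstate(invalid="ignore"):
        err = np.sqrt(F_protonated.error ** 2 + F_neutral_shifted.error ** 2)
    err[~both] = np.nan
    return FreeEnergySurface(F_protonated.axes, dF, err, both, "none",
                             F_protonated.thermo, F_protonated.bulk_cut,
                             F_protonated.labels)
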