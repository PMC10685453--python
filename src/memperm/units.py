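"""Unit system and thermodynamic state.

The project-wide unit convention is the PLUMED one: lengths in Å, times
in ps, energies in kJ·mol⁻¹, temperatures in K.  Diffusion coefficients
are therefore Å²·ps⁻¹ and permeabilities are converted to cm·s⁻¹ only at
the reporting boundary (1 Å·ps⁻¹ = 10⁴ cm·s⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Gas constant in kJ·mol⁻¹·K⁻¹ (PLUMED / GROMACS convention).
R_KJ_MOL_K = 0.0083144621

#: 1 debye in C·m.
DEBYE_CM = 3.33564e-30

#: Avogadro constant, mol⁻¹.
N_AVOGADRO = 6.02214076e23

#: Conversion factor: 1 Å·ps⁻¹ expressed in cm·s⁻¹.
ANG_PER_PS_TO_CM_PER_S = 1.0e4


@dataclass(frozen=True)
class ThermoState:
    """Temperature and derived energy scales used by every estimator.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin; must be positive.

    Attributes
    ----------
    kT : float
        Thermal energy R·T in kJ·mol⁻¹.
    beta : float
        Inverse thermal energy 1/kT in mol·kJ⁻¹.
    """

    temperature: float = 310.0
    kT: float = field(init=False)
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        object.__setattr__(self, "kT", R_KJ_MOL_K * self.temperature)
        object.__setattr__(self, "beta", 1.0 / self.kT)
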