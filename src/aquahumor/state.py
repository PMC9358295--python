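"""Compartment states: concentrations, potential and (cell only) fixed charge.

Concentrations are kept in mM throughout, which is numerically identical to the
SI mol/m^3; potentials are stored in volts.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import N_SPECIES, VALENCES, Species


@dataclass
class CompartmentState:
    """State of one well-mixed compartment (stroma, cell or posterior chamber).

    Parameters
    ----------
    conc
        Concentrations of the seven species in mM, in :class:`~aquahumor.constants.Species`
        order.
    potential
        Electric potential in volts (the stroma is the ground, 0 V).
    c_fixed
        Concentration of non-diffusible fixed charge X in mM. Only meaningful
        for the cellular compartment; zero elsewhere.
    z_fixed
        Valence of the fixed charge (dimensionless, negative).
    """

    conc: np.ndarray
    potential: float = 0.0
    c_fixed: float = 0.0
    z_fixed: float = -1.5

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        if self.conc.shape != (N_SPECIES,):
            raise ValueError(f"expected {N_SPECIES} concentrations, got {self.conc.shape}")

    def charge_concentration(self) -> float:
        """Net charge concentration sum(z_i C_i) + z_X C_X (mM of charge)."""
        return float(VALENCES @ self.conc + self.z_fixed * self.c_fixed)

    def osmolarity(self) -> float:
        """Total osmolarity (mM), counting all seven solutes plus fixed charge."""
        return float(self.conc.sum() + self.c_fixed)

    @property
    def ph(self) -> float:
        """pH = -log10([H+] in molar); concentrations are stored in mM."""
        return float(-np.log10(self.conc[Species.H] * 1e-3))

    def copy(self) -> "CompartmentState":
        return replace(self, conc=self.conc.copy())


def h_conc_from_ph(ph: float) -> float:
    """H+ concentration in mM corresponding to a pH value."""
    return 10.0 ** (-ph + 3.0)


def make_stroma(
    na: float,
    k: float,
    cl: float,
    hco3: float,
    ph: float,
    kd_assoc: float,
    kd_rate: float,
    kh_rate: float,
    potential: float = 0.0,
    balance_cl: bool = True,
) -> CompartmentState:
    """Build a reaction-consistent, electroneutral stromal boundary state.

    H+ comes from the pH; H2CO3 from the fast association equilibrium
    C_H2CO3 = K_d * C_H * C_HCO3; CO2 from the slow-step equilibrium
    C_CO2 = (k_d / k_h) * C_H2CO3. The major ions are given explicitly. When
    ``balance_cl`` is set, the residual charge (of order C_H, i.e. far below
    printed precision) is absorbed into Cl- so that the imposed boundary is
    exactly electroneutral.
    """
    ch = h_conc_from_ph(ph)
    h2co3 = kd_assoc * ch * hco3
    co2 = (kd_rate / kh_rate) * h2co3
    conc = np.array([na, k, cl, hco3, ch, co2, h2co3])
    state = CompartmentState(conc=conc, potential=potential)
    residual = state.charge_concentration()
    if abs(residual) > 1e-3:
        raise ValueError(
            f"stromal boundary is not electroneutral: sum z_i C_i = {residual:.3g} mM"
        )
    if balance_cl:
        state.conc[Species.CL] += residual
    return state
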