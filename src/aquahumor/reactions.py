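"""Carbonate buffer kinetics and the fast-equilibrium reduction.

The buffer chain is HCO3- + H+ <-> H2CO3 <-> CO2 + H2O. The first
(association) step is effectively instantaneous, so it is never evaluated
kinetically: the model imposes C_H2CO3 = K_d C_H C_HCO3 as an algebraic
constraint and tracks only combinations of species conserved by the fast step.
The second (de/hydration) step is slow unless catalysed by carbonic anhydrase
and is the only kinetic rate in the system.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import N_SPECIES, VALENCES, Species
from .state import CompartmentState


@dataclass
class ReactionRates:
    """Volumetric production rates R_i (mM/s) of each species in one compartment.

    Only the slow de/hydration step contributes; the fast association step is
    handled as an equilibrium constraint, so its (formally infinite) rate never
    appears here.
    """

    rates: np.ndarray

    def charge_rate(self) -> float:
        """sum(z_i R_i); zero because the reactions conserve charge."""
        return float(VALENCES @ self.rates)

    def carbon_rate(self) -> float:
        """R_HCO3 + R_H2CO3 + R_CO2; zero because carbon is conserved."""
        return float(
            self.rates[Species.HCO3] + self.rates[Species.H2CO3] + self.rates[Species.CO2]
        )


def dehydration_rate(state: CompartmentState, k_dehyd: float, k_hyd: float) -> float:
    """Net slow-step rate s = k_d C_H2CO3 - k_h C_CO2 (mM/s), H2CO3 -> CO2 positive.

    Water activity is absorbed into k_h.
    """
    if k_dehyd < 0 or k_hyd < 0:
        raise ValueError("rate constants must be non-negative")
    return k_dehyd * state.conc[Species.H2CO3] - k_hyd * state.conc[Species.CO2]


def reaction_rates(
    state: CompartmentState,
    k_dehyd: float,
    k_hyd: float,
    kd_assoc: float,
    ca_active: bool = True,
    ca_inhibition_factor: float = 1e6,
) -> ReactionRates:
    """Mass-action production rates of the slow step for one compartment.

    When ``ca_active`` is False both k_d and k_h are divided by
    ``ca_inhibition_factor``, emulating carbonic anhydrase inhibition.
    """
    if not ca_active:
        k_dehyd = k_dehyd / ca_inhibition_factor
        k_hyd = k_hyd / ca_inhibition_factor
    s = dehydration_rate(state, k_dehyd, k_hyd)
    rates = np.zeros(N_SPECIES)
    rates[Species.H2CO3] = -s
    rates[Species.CO2] = s
    return ReactionRates(rates=rates)


def equilibrium_h2co3(c_h: float, c_hco3: float, kd_assoc: float) -> float:
    """H2CO3 concentration at fast equilibrium, C_H2CO3 = K_d C_H C_HCO3 (mM)."""
    return kd_assoc * c_h * c_hco3


def split_carbonate_totals(
    b_hco3: float, b_h: float, kd_assoc: float
) -> tuple[float, float, float]:
    """Recover (C_HCO3, C_H, C_H2CO3) from fast-reaction invariants.

    ``b_hco3`` = C_HCO3 + C_H2CO3 and ``b_h`` = C_H + C_H2CO3 are conserved by
    the association step. Substituting the equilibrium relation gives a
    quadratic K_d x^2 - (K_d (b_hco3 + b_h) + 1) x + K_d b_hco3 b_h = 0 for
    x = C_H2CO3, solved with the cancellation-safe root formula (x is tiny
    relative to b_hco3, so the naive formula would lose all precision in H+).
    """
    a = kd_assoc
    b = -(kd_assoc * (b_hco3 + b_h) + 1.0)
    c = kd_assoc * b_hco3 * b_h
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ValueError("no real carbonate equilibrium for the given totals")
    x = 2.0 * c / (-b + np.sqrt(disc))
    return b_hco3 - x, b_h - x, x
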