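"""Solute and water flux laws for every pathway across the three membranes.

Sign convention: every flux returned here is positive in the direction from the
first state argument to the second. At the model level all pathways are
oriented stroma -> cell, cell -> PC, and stroma -> PC (tight junction), so a
positive number always means secretion-directed transport. The figure-style
"positive out of the cell" view is a reporting transform applied elsewhere.

Channels use the Goldman-Hodgkin-Katz constant-field flux; coupled
transporters use log mass-action (electro)chemical quotients; the Na+/K+
ATPase uses saturable Michaelis-Menten kinetics in intracellular Na+ and
external K+.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import FARADAY, N_SPECIES, R_GAS, VALENCES, Species
from .parameters import ModelParameters
from .state import CompartmentState

#: Concentration floor (mM) applied inside logarithmic quotients.
LOG_CLAMP_MM = 1e-12


class ConcentrationClampWarning(UserWarning):
    """A non-positive concentration entered a log quotient and was clamped."""


def _clamped(conc: float, species: str, transporter: str) -> float:
    if conc <= LOG_CLAMP_MM:
        warnings.warn(
            f"{transporter}: {species} concentration {conc:.3g} mM clamped to "
            f"{LOG_CLAMP_MM} mM inside log quotient",
            ConcentrationClampWarning,
            stacklevel=3,
        )
        return LOG_CLAMP_MM
    return conc


def _log_ratio(numer: float, denom: float, transporter: str, species: str) -> float:
    return np.log(
        _clamped(numer, species, transporter) / _clamped(denom, species, transporter)
    )


def thermal_voltage(temperature: float) -> float:
    """RT/F in volts."""
    return R_GAS * temperature / FARADAY


def electrodiffusive_flux(
    species: Species,
    permeability: float,
    area: float,
    from_state: CompartmentState,
    to_state: CompartmentState,
    temperature: float,
) -> float:
    """GHK constant-field flux of an ion through a channel (mol/s).

    For the membrane potential difference dV = V_from - V_to and reduced
    potential phi = z F dV / RT the flux density is
    P * phi * (C_from - C_to exp(-phi)) / (1 - exp(-phi)); the removable
    singularity at phi -> 0 reduces to the Fickian limit P (C_from - C_to).
    Uncharged species (z = 0) fall through to plain diffusion.
    """
    if permeability < 0 or area < 0:
        raise ValueError("permeability and area must be non-negative")
    z = VALENCES[species]
    cm = from_state.conc[species]
    ck = to_state.conc[species]
    if z == 0:
        return area * permeability * (cm - ck)
    phi = z * FARADAY * (from_state.potential - to_state.potential) / (
        R_GAS * temperature
    )
    if abs(phi) < 1e-10:
        # second-order series around phi = 0
        g = (cm - ck) + 0.5 * phi * (cm + ck)
    elif phi > 0:
        g = phi * (cm - ck * np.exp(-phi)) / -np.expm1(-phi)
    else:
        # rewritten with exp(phi) <= 1 so large negative phi cannot overflow
        g = phi * (cm * np.exp(phi) - ck) / np.expm1(phi)
    return area * permeability * g


def uncharged_diffusive_flux(
    species: Species,
    permeability: float,
    area: float,
    from_state: CompartmentState,
    to_state: CompartmentState,
) -> float:
    """Fickian flux of CO2 or H2CO3 across a membrane (mol/s)."""
    if permeability < 0 or area < 0:
        raise ValueError("permeability and area must be non-negative")
    return area * permeability * (from_state.conc[species] - to_state.conc[species])


def pump_flux(
    p_pump: float,
    area: float,
    cell: CompartmentState,
    pc: CompartmentState,
    params: ModelParameters,
) -> tuple[float, float]:
    """Na+/K+ ATPase on the PC membrane: (J_Na, J_K) in mol/s, cell -> PC positive.

    Extrudes 3 Na+ from the cell and imports 2 K+ per cycle. The turnover
    saturates in intracellular Na+ and PC-side K+ with half-saturation
    constants that depend on the trans-side competitor (Strieter-Weinstein
    kinetics): K_Na = 0.2 (1 + C_K^c / 8.33) mM, K_K = 0.1 (1 + C_Na^p / 18.5) mM.
    """
    if p_pump < 0:
        raise ValueError("pump intensity must be non-negative")
    na_c = max(cell.conc[Species.NA], 0.0)
    k_p = max(pc.conc[Species.K], 0.0)
    km_na = params.pump_km_na * (1.0 + max(cell.conc[Species.K], 0.0) / params.pump_k_kc)
    km_k = params.pump_km_k * (1.0 + max(pc.conc[Species.NA], 0.0) / params.pump_k_nap)
    turnover = (na_c / (na_c + km_na)) ** 3 * (k_p / (k_p + km_k)) ** 2
    rate = area * p_pump * turnover
    return 3.0 * rate, -2.0 * rate


def nkcc_flux(
    p_nkcc: float,
    area: float,
    stroma: CompartmentState,
    cell: CompartmentState,
) -> tuple[float, float, float]:
    """Na+/K+/2Cl- cotransporter on the stromal membrane: (J_Na, J_K, J_Cl).

    Electroneutral, so driven purely by the mass-action quotient
    ln[(Na_s K_s Cl_s^2)/(Na_c K_c Cl_c^2)]; positive into the cell.
    """
    f = (
        _log_ratio(stroma.conc[Species.NA], cell.conc[Species.NA], "nkcc", "Na+")
        + _log_ratio(stroma.conc[Species.K], cell.conc[Species.K], "nkcc", "K+")
        + 2.0 * _log_ratio(stroma.conc[Species.CL], cell.conc[Species.CL], "nkcc", "Cl-")
    )
    j = area * p_nkcc * f
    return j, j, 2.0 * j


def anion_exchanger_flux(
    p_ae: float,
    area: float,
    side_a: CompartmentState,
    side_b: CompartmentState,
) -> tuple[float, float]:
    """Cl-/HCO3- exchanger: (J_Cl, J_HCO3) positive a -> b, with J_HCO3 = -J_Cl.

    Oriented so that Cl- moves a -> b (and HCO3- b -> a) when the quotient
    (Cl_a HCO3_b)/(Cl_b HCO3_a) exceeds one. Instantiated as ``aes`` with the
    stroma on side a (Cl- uptake, HCO3- extrusion from the cell) and as
    ``aep`` with the cell on side b (HCO3- secretion into the PC appears as a
    negative a->b Cl- flux from the PC side; see the assembler).
    """
    f = _log_ratio(side_a.conc[Species.CL], side_b.conc[Species.CL], "ae", "Cl-") + _log_ratio(
        side_b.conc[Species.HCO3], side_a.conc[Species.HCO3], "ae", "HCO3-"
    )
    j_cl = area * p_ae * f
    return j_cl, -j_cl


def nhe_flux(
    p_nhe: float,
    area: float,
    stroma: CompartmentState,
    cell: CompartmentState,
) -> tuple[float, float]:
    """Na+/H+ exchanger on the stromal membrane: (J_Na, J_H), stroma -> cell.

    Electroneutral 1:1 exchange: Na+ enters the cell while H+ is extruded,
    driven by ln[(Na_s H_c)/(Na_c H_s)]; J_H = -J_Na.
    """
    f = _log_ratio(stroma.conc[Species.NA], cell.conc[Species.NA], "nhe", "Na+") + _log_ratio(
        cell.conc[Species.H], stroma.conc[Species.H], "nhe", "H+"
    )
    j_na = area * p_nhe * f
    return j_na, -j_na


def nbc_flux(
    p_nbc: float,
    area: float,
    side_a: CompartmentState,
    side_b: CompartmentState,
    temperature: float,
) -> tuple[float, float]:
    """Na+/(HCO3-)2 cotransporter: (J_Na, J_HCO3) positive a -> b.

    Stoichiometry 1:2 gives the carrier a net charge of -1, so the driving
    force is the electrochemical quotient
    ln[(Na_a HCO3_a^2)/(Na_b HCO3_b^2)] - F (V_a - V_b) / RT,
    and J_HCO3 = 2 J_Na.
    """
    f = (
        _log_ratio(side_a.conc[Species.NA], side_b.conc[Species.NA], "nbc", "Na+")
        + 2.0
        * _log_ratio(side_a.conc[Species.HCO3], side_b.conc[Species.HCO3], "nbc", "HCO3-")
        - FARADAY * (side_a.potential - side_b.potential) / (R_GAS * temperature)
    )
    j_na = area * p_nbc * f
    return j_na, 2.0 * j_na


def water_flux(
    k_hydraulic: float,
    sigma: float,
    area: float,
    from_state: CompartmentState,
    to_state: CompartmentState,
    temperature: float,
) -> float:
    """Osmotic water flux Q = -A K sigma R T (osm_from - osm_to) in m^3/s.

    Positive toward the hyperosmotic destination; osmolarity counts all seven
    solutes plus the fixed charge where the cell is involved. The van't Hoff
    factor R T converts mM (= mol/m^3) to Pa.
    """
    if k_hydraulic < 0 or area < 0:
        raise ValueError("hydraulic conductivity and area must be non-negative")
    dc = from_state.osmolarity() - to_state.osmolarity()
    return -area * k_hydraulic * sigma * R_GAS * temperature * dc


@dataclass
class MembraneFluxes:
    """Per-species, per-pathway solute fluxes across the three membranes.

    ``stromal``, ``pc`` and ``tj`` map pathway name -> length-7 species flux
    vector (mol/s), positive stroma->cell, cell->PC and stroma->PC
    respectively. ``total(membrane)`` sums the pathways.
    """

    stromal: dict[str, np.ndarray] = field(default_factory=dict)
    pc: dict[str, np.ndarray] = field(default_factory=dict)
    tj: dict[str, np.ndarray] = field(default_factory=dict)

    def total(self, membrane: str) -> np.ndarray:
        pathways = getattr(self, membrane)
        out = np.zeros(N_SPECIES)
        for flux in pathways.values():
            out += flux
        return out


def assemble_membrane_fluxes(
    params: ModelParameters,
    stroma: CompartmentState,
    cell: CompartmentState,
    pc: CompartmentState,
) -> MembraneFluxes:
    """Evaluate every pathway on all three membranes for the given states.

    Stromal membrane: nkcc, aes, nhe, nbcs, K+ channel, CO2/H2CO3 diffusion.
    PC membrane: pump, aep, nbcp, K+ and Cl- channels, CO2/H2CO3 diffusion.
    Tight junction: GHK electrodiffusion of Na+, K+, Cl-, HCO3- (shared
    permeability) plus CO2/H2CO3 diffusion.
    """
    T = params.temperature
    out = MembraneFluxes()

    def vec(**species_fluxes: float) -> np.ndarray:
        v = np.zeros(N_SPECIES)
        for name, value in species_fluxes.items():
            v[Species[name.upper()]] = value
        return v

    # --- stromal membrane (stroma -> cell positive) ---
    j_na, j_k, j_cl = nkcc_flux(params.p_nkcc, params.area_s, stroma, cell)
    out.stromal["nkcc"] = vec(na=j_na, k=j_k, cl=j_cl)
    j_cl, j_hco3 = anion_exchanger_flux(params.p_aes, params.area_s, stroma, cell)
    out.stromal["aes"] = vec(cl=j_cl, hco3=j_hco3)
    j_na, j_h = nhe_flux(params.p_nhe, params.area_s, stroma, cell)
    out.stromal["nhe"] = vec(na=j_na, h=j_h)
    j_na, j_hco3 = nbc_flux(params.p_nbcs, params.area_s, stroma, cell, T)
    out.stromal["nbcs"] = vec(na=j_na, hco3=j_hco3)
    out.stromal["k_channel"] = vec(
        k=electrodiffusive_flux(Species.K, params.p_k_s, params.area_s, stroma, cell, T)
    )
    out.stromal["co2"] = vec(
        co2=uncharged_diffusive_flux(Species.CO2, params.p_co2_s, params.area_s, stroma, cell)
    )
    out.stromal["h2co3"] = vec(
        h2co3=uncharged_diffusive_flux(
            Species.H2CO3, params.p_h2co3_s, params.area_s, stroma, cell
        )
    )

    # --- PC membrane (cell -> PC positive) ---
    j_na, j_k = pump_flux(params.p_pump, params.area_p, cell, pc, params)
    out.pc["pump"] = vec(na=j_na, k=j_k)
    # aep physiologically runs Cl- PC->cell / HCO3- cell->PC; evaluate with the
    # PC on side a, then flip signs into the cell->PC convention of this membrane.
    j_cl_pc_to_cell, j_hco3_pc_to_cell = anion_exchanger_flux(
        params.p_aep, params.area_p, pc, cell
    )
    out.pc["aep"] = vec(cl=-j_cl_pc_to_cell, hco3=-j_hco3_pc_to_cell)
    j_na, j_hco3 = nbc_flux(params.p_nbcp, params.area_p, cell, pc, T)
    out.pc["nbcp"] = vec(na=j_na, hco3=j_hco3)
    out.pc["k_channel"] = vec(
        k=electrodiffusive_flux(Species.K, params.p_k_p, params.area_p, cell, pc, T)
    )
    out.pc["cl_channel"] = vec(
        cl=electrodiffusive_flux(Species.CL, params.p_cl_p, params.area_p, cell, pc, T)
    )
    out.pc["co2"] = vec(
        co2=uncharged_diffusive_flux(Species.CO2, params.p_co2_p, params.area_p, cell, pc)
    )
    out.pc["h2co3"] = vec(
        h2co3=uncharged_diffusive_flux(Species.H2CO3, params.p_h2co3_p, params.area_p, cell, pc)
    )

    # --- tight junction (stroma -> PC positive) ---
    tj_ions = np.zeros(N_SPECIES)
    for sp in (Species.NA, Species.K, Species.CL, Species.HCO3):
        tj_ions[sp] = electrodiffusive_flux(sp, params.p_tj, params.area_tj, stroma, pc, T)
    out.tj["electrodiffusion"] = tj_ions
    out.tj["co2"] = vec(
        co2=uncharged_diffusive_flux(Species.CO2, params.p_co2_s, params.area_tj, stroma, pc)
    )
    out.tj["h2co3"] = vec(
        h2co3=uncharged_diffusive_flux(
            Species.H2CO3, params.p_h2co3_s, params.area_tj, stroma, pc
        )
    )
    return out
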