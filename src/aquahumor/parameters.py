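"""Model parameters: geometry, permeabilities, transporter intensities, kinetics.

All values are stored in SI units internally. The conventional reporting units
(intensities in 1e-6 mol/m^2/s, channel permeabilities in 1e-8 m/s) are applied
once, at configuration load.
"""
from __future__ import annotations

from dataclasses import dataclass, fields, replace

#: Scale factor between reported transporter intensities and SI mol/m^2/s.
INTENSITY_SCALE = 1e-6
#: Scale factor between reported channel permeabilities and SI m/s.
PERMEABILITY_SCALE = 1e-8

#: The ten channel/transporter parameters varied in the global sensitivity
#: analysis (the pump intensity is deliberately excluded and held fixed).
SENSITIVITY_PARAMETERS = (
    "p_nkcc",
    "p_aes",
    "p_aep",
    "p_nbcp",
    "p_nbcs",
    "p_nhe",
    "p_k_s",
    "p_k_p",
    "p_cl_p",
    "p_tj",
)


@dataclass
class ModelParameters:
    """All scalar parameters of the compartmental model (SI units).

    Attributes are grouped as in the shipped configuration: geometry,
    hydraulic conductivities, CO2/H2CO3 permeabilities, reaction constants,
    transporter intensities, channel permeabilities, and the saturable pump
    kinetics constants.
    """

    # --- geometry (m, m^2) ---
    cell_height: float = 1e-5          # L: epithelial cell layer thickness
    pc_length: float = 6e-3            # H: posterior-chamber length scale
    area_s: float = 6e-4               # A^s~: stromal membrane area
    area_p: float = 6e-4               # A^p~: PC membrane area
    area_tj: float = 6e-7              # A^tj: tight-junction area
    area_pc: float = 2.6e-5            # A^PC: posterior chamber cross-section

    # --- hydraulic conductivities (m/s/Pa) ---
    k_water_s: float = 2e-11
    k_water_tj: float = 2e-11
    k_water_p: float = 2e-10

    # --- CO2 / H2CO3 membrane permeabilities (m/s); tj shares stromal values ---
    p_co2_s: float = 1.5e-3
    p_co2_p: float = 1.5e-2
    p_h2co3_s: float = 1.28e-5
    p_h2co3_p: float = 1.28e-4

    # --- carbonate reaction constants ---
    k_dehyd: float = 4.96e5            # k_d (1/s), H2CO3 -> CO2 + H2O (CA-catalysed)
    k_hyd: float = 1.45e3              # k_h (1/s), CO2 + H2O -> H2CO3 (CA-catalysed)
    kd_assoc: float = 5.3              # K_d = k_1/k_-1 (1/mM), HCO3- + H+ <-> H2CO3

    # --- other ---
    temperature: float = 310.0         # K
    sigma: float = 1.0                 # osmotic reflection coefficient for ions
    z_fixed: float = -1.5              # valence of cellular fixed charge

    # --- transporter intensities (mol/m^2/s) ---
    p_pump: float = 6e-6
    p_nkcc: float = 1e-6
    p_aes: float = 4e-6
    p_aep: float = 0.4e-6
    p_nbcp: float = 0.98e-6
    p_nbcs: float = 0.6e-6
    p_nhe: float = 3.4e-6

    # --- channel permeabilities (m/s) ---
    p_k_s: float = 5e-8
    p_k_p: float = 30e-8
    p_cl_p: float = 6e-8
    p_tj: float = 600e-8

    # --- Na+/K+ pump saturation constants (mM), Strieter-Weinstein kinetics ---
    pump_km_na: float = 0.2            # K_Na = pump_km_na * (1 + C_K^c / pump_k_kc)
    pump_k_kc: float = 8.33
    pump_km_k: float = 0.1             # K_K = pump_km_k * (1 + C_Na^p / pump_k_nap)
    pump_k_nap: float = 18.5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name == "z_fixed":
                if value >= 0:
                    raise ValueError("z_fixed must be negative")
                continue
            if value <= 0:
                raise ValueError(f"parameter {f.name} must be strictly positive, got {value}")
        if not 0 < self.sigma <= 1:
            raise ValueError(f"sigma must lie in (0, 1], got {self.sigma}")

    def with_scaled(self, **factors: float) -> "ModelParameters":
        """Return a copy with named parameters multiplied by the given factors."""
        updates = {}
        for name, factor in factors.items():
            if not hasattr(self, name):
                raise KeyError(f"unknown model parameter: {name!r}")
            updates[name] = getattr(self, name) * factor
        return replace(self, **updates)

    def without_ca(self, factor: float = 1e6) -> "ModelParameters":
        """Copy with carbonic anhydrase inhibited: k_d and k_h divided by ``factor``."""
        return replace(self, k_dehyd=self.k_dehyd / factor, k_hyd=self.k_hyd / factor)
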