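"""Configuration loading, result tables and the reproducibility manifest."""
from __future__ import annotations

import datetime as _dt
import hashlib
import json
import sys
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import Species
from .parameters import INTENSITY_SCALE, PERMEABILITY_SCALE, ModelParameters
from .sensitivity import SensitivityConfig
from .solver import SolverConfig, SteadyStateSolution
from .state import CompartmentState, make_stroma


class ConfigError(ValueError):
    """A malformed or physically inconsistent configuration file."""


def default_config_path() -> Path:
    """Path of the shipped baseline configuration."""
    return Path(str(resources.files("aquahumor").joinpath("data/baseline.yaml")))


def _require(section: dict, key: str, where: str):
    try:
        return section[key]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"missing field {key!r} in config section {where!r}") from exc


def load_config(
    path: str | Path | None = None,
) -> tuple[ModelParameters, CompartmentState, SolverConfig, SensitivityConfig]:
    """Load and validate a model configuration.

    Reads the YAML file (the shipped baseline when ``path`` is None), applies
    the conventional unit scalings (intensities 1e-6 mol/m^2/s, channel
    permeabilities 1e-8 m/s, stromal potential mV), derives the stromal H+,
    H2CO3 and CO2 concentrations from pH and the buffer equilibria, and
    verifies stromal electroneutrality.
    """
    cfg_path = Path(path) if path is not None else default_config_path()
    with open(cfg_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{cfg_path}: not a mapping")

    geo = _require(raw, "geometry", "top level")
    water = _require(raw, "water_permeability", "top level")
    gas = _require(raw, "gas_permeability", "top level")
    rr = _require(raw, "reaction_rates", "top level")
    other = _require(raw, "other", "top level")
    ions = _require(raw, "ion_transport", "top level")
    intens = _require(ions, "intensities", "ion_transport")
    perms = _require(ions, "permeabilities", "ion_transport")
    pump = raw.get("pump_kinetics", {})
    stroma_cfg = _require(raw, "stroma", "top level")

    try:
        params = ModelParameters(
            cell_height=float(_require(geo, "L", "geometry")),
            pc_length=float(_require(geo, "H", "geometry")),
            area_s=float(_require(geo, "A_s", "geometry")),
            area_p=float(_require(geo, "A_p", "geometry")),
            area_tj=float(_require(geo, "A_tj", "geometry")),
            area_pc=float(_require(geo, "A_pc", "geometry")),
            k_water_s=float(_require(water, "K_s", "water_permeability")),
            k_water_tj=float(_require(water, "K_tj", "water_permeability")),
            k_water_p=float(_require(water, "K_p", "water_permeability")),
            p_co2_s=float(_require(gas, "P_co2_s", "gas_permeability")),
            p_co2_p=float(_require(gas, "P_co2_p", "gas_permeability")),
            p_h2co3_s=float(_require(gas, "P_h2co3_s", "gas_permeability")),
            p_h2co3_p=float(_require(gas, "P_h2co3_p", "gas_permeability")),
            k_dehyd=float(_require(rr, "k_d", "reaction_rates")),
            k_hyd=float(_require(rr, "k_h", "reaction_rates")),
            kd_assoc=float(_require(rr, "K_d", "reaction_rates")),
            temperature=float(_require(other, "T", "other")),
            sigma=float(_require(other, "sigma", "other")),
            z_fixed=float(_require(other, "z_X", "other")),
            p_pump=float(_require(intens, "P_pump", "intensities")) * INTENSITY_SCALE,
            p_nkcc=float(_require(intens, "P_nkcc", "intensities")) * INTENSITY_SCALE,
            p_aes=float(_require(intens, "P_aes", "intensities")) * INTENSITY_SCALE,
            p_aep=float(_require(intens, "P_aep", "intensities")) * INTENSITY_SCALE,
            p_nbcp=float(_require(intens, "P_nbcp", "intensities")) * INTENSITY_SCALE,
            p_nbcs=float(_require(intens, "P_nbcs", "intensities")) * INTENSITY_SCALE,
            p_nhe=float(_require(intens, "P_nhe", "intensities")) * INTENSITY_SCALE,
            p_k_s=float(_require(perms, "P_K_s", "permeabilities")) * PERMEABILITY_SCALE,
            p_k_p=float(_require(perms, "P_K_p", "permeabilities")) * PERMEABILITY_SCALE,
            p_cl_p=float(_require(perms, "P_Cl_p", "permeabilities")) * PERMEABILITY_SCALE,
            p_tj=float(_require(perms, "P_tj", "permeabilities")) * PERMEABILITY_SCALE,
            pump_km_na=float(pump.get("km_na", 0.2)),
            pump_k_kc=float(pump.get("k_kc", 8.33)),
            pump_km_k=float(pump.get("km_k", 0.1)),
            pump_k_nap=float(pump.get("k_nap", 18.5)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    try:
        stroma = make_stroma(
            na=float(_require(stroma_cfg, "Na", "stroma")),
            k=float(_require(stroma_cfg, "K", "stroma")),
            cl=float(_require(stroma_cfg, "Cl", "stroma")),
            hco3=float(_require(stroma_cfg, "HCO3", "stroma")),
            ph=float(_require(stroma_cfg, "pH", "stroma")),
            kd_assoc=params.kd_assoc,
            kd_rate=params.k_dehyd,
            kh_rate=params.k_hyd,
            potential=float(stroma_cfg.get("V_mV", 0.0)) * 1e-3,
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    sv = raw.get("solver", {})
    solver_config = SolverConfig(
        tolerance=float(sv.get("tolerance", 1e-9)),
        max_iterations=int(sv.get("max_iterations", 400)),
        multistart=int(sv.get("multistart", 20)),
        seed=int(sv.get("seed", 1234)),
    )
    sens = raw.get("sensitivity", {})
    sensitivity_config = SensitivityConfig(
        range_fraction=float(sens.get("range_fraction", 0.5)),
        samples_per_curve=int(sens.get("samples_per_curve", 1991)),
        resamples=int(sens.get("resamples", 3)),
        interference=int(sens.get("interference", 4)),
        seed=int(sens.get("seed", 0)),
    )
    return params, stroma, solver_config, sensitivity_config


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["Na+ (mM)", "K+ (mM)", "Cl- (mM)", "HCO3- (mM)", "pH", "V (mV)"]


def concentration_table(
    solutions: dict[str, SteadyStateSolution]
) -> pd.DataFrame:
    """Concentrations, pH and potential per compartment, one block per solution.

    Mirrors the conventional reporting layout: rows Stroma / Cell / PC with
    the major-ion concentrations in mM, pH and the potential in mV.
    """
    rows, index = [], []
    for label, sol in solutions.items():
        for name, state in (("Stroma", sol.stroma), ("Cell", sol.cell), ("PC", sol.pc)):
            rows.append(
                [
                    state.conc[Species.NA],
                    state.conc[Species.K],
                    state.conc[Species.CL],
                    state.conc[Species.HCO3],
                    state.ph,
                    state.potential * 1e3,
                ]
            )
            index.append((label, name))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["run", "compartment"]),
        columns=_TABLE_COLUMNS,
    )


def flux_table(solutions: dict[str, SteadyStateSolution]) -> pd.DataFrame:
    """Transepithelial ion fluxes (umol/m^2/s) and water flux (m^3/s) per run."""
    rows = []
    for label, sol in solutions.items():
        ions = sol.transepithelial_ion_fluxes()
        rows.append(
            {
                "run": label,
                "Na+": ions[Species.NA],
                "K+": ions[Species.K],
                "Cl-": ions[Species.CL],
                "HCO3-": ions[Species.HCO3],
                "H2O (m^3/s)": sol.water_flux,
            }
        )
    return pd.DataFrame(rows).set_index("run")


def render_tables(
    solutions: dict[str, SteadyStateSolution], out_dir: str | Path
) -> dict[str, Path]:
    """Write the concentration and flux tables as CSV files; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "concentrations": out / "concentrations.csv",
        "fluxes": out / "fluxes.csv",
    }
    concentration_table(solutions).to_csv(paths["concentrations"])
    flux_table(solutions).to_csv(paths["fluxes"])
    return paths


@dataclass
class RunManifest:
    """Provenance record attached to every output directory."""

    config_hash: str
    seed: int | None
    version: str
    timestamp: str
    command: str

    @classmethod
    def create(cls, config_path: str | Path | None, seed: int | None) -> "RunManifest":
        from . import __version__

        path = Path(config_path) if config_path is not None else default_config_path()
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        return cls(
            config_hash=digest,
            seed=seed,
            version=__version__,
            timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
            command=" ".join(sys.argv),
        )

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "manifest.json"
        path.write_text(json.dumps(self.__dict__, indent=2) + "\n")
        return path
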