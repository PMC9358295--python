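"""Drivers for the in-silico experiments: baseline, CA inhibition, knockdowns.

Each driver returns an :class:`ExperimentResult` holding the paired reference
and perturbed steady states, from which all reported deltas are recomputable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import Species
from .parameters import ModelParameters
from .solver import SolverConfig, SteadyStateSolution, solve_steady_state
from .state import CompartmentState


@dataclass
class PerturbationSpec:
    """A multiplicative perturbation of named parameters, and/or CA inhibition."""

    factors: dict[str, float] = field(default_factory=dict)
    inhibit_ca: bool = False
    ca_factor: float = 1e6

    def __post_init__(self) -> None:
        for name, factor in self.factors.items():
            if factor <= 0:
                raise ValueError(f"perturbation factor for {name!r} must be positive")

    def apply(self, params: ModelParameters) -> ModelParameters:
        out = params.with_scaled(**self.factors) if self.factors else params
        if self.inhibit_ca:
            out = out.without_ca(self.ca_factor)
        return out


@dataclass
class ExperimentResult:
    """Paired steady states (reference, optionally perturbed) plus deltas."""

    reference: SteadyStateSolution
    perturbed: SteadyStateSolution | None = None
    label: str = "baseline"

    @property
    def delta_q_percent(self) -> float:
        """Relative change of the production rate, 100 (Q' - Q) / Q."""
        if self.perturbed is None:
            raise ValueError("no perturbed solution in this result")
        return 100.0 * (self.perturbed.water_flux / self.reference.water_flux - 1.0)

    def concentration_changes(self) -> pd.DataFrame:
        """Per-species concentration changes (mM) in cell and PC."""
        if self.perturbed is None:
            raise ValueError("no perturbed solution in this result")
        from .constants import SPECIES_NAMES

        return pd.DataFrame(
            {
                "cell": self.perturbed.cell.conc - self.reference.cell.conc,
                "pc": self.perturbed.pc.conc - self.reference.pc.conc,
            },
            index=SPECIES_NAMES,
        )


def run_baseline(
    params: ModelParameters,
    stroma: CompartmentState,
    solver_config: SolverConfig | None = None,
) -> ExperimentResult:
    """Solve the model at the shipped baseline parameters (reference only)."""
    return ExperimentResult(
        reference=solve_steady_state(params, stroma, solver_config), label="baseline"
    )


def inhibit_ca(
    params: ModelParameters,
    stroma: CompartmentState,
    solver_config: SolverConfig | None = None,
    factor: float = 1e6,
) -> ExperimentResult:
    """Baseline vs carbonic anhydrase inhibition (k_d, k_h divided by 1e6)."""
    reference = solve_steady_state(params, stroma, solver_config)
    perturbed = solve_steady_state(
        params.without_ca(factor), stroma, solver_config, initial_guess=reference.unknowns
    )
    return ExperimentResult(reference=reference, perturbed=perturbed, label="ca-inhibition")


def scale_parameter(
    params: ModelParameters,
    stroma: CompartmentState,
    spec: PerturbationSpec,
    solver_config: SolverConfig | None = None,
) -> ExperimentResult:
    """Generic single/multi-parameter scaling experiment (e.g. pump knockdown)."""
    reference = solve_steady_state(params, stroma, solver_config)
    perturbed = solve_steady_state(
        spec.apply(params), stroma, solver_config, initial_guess=reference.unknowns
    )
    label = ",".join(f"{k}x{v:g}" for k, v in spec.factors.items()) or "identity"
    if spec.inhibit_ca:
        label += "+noCA"
    return ExperimentResult(reference=reference, perturbed=perturbed, label=label)


#: (membrane, pathway, species) -> sign mapping the internal secretion-directed
#: convention onto the figure convention "positive out of the cell" (for the
#: exchangers: positive if HCO3- leaves the cell; for nhe: positive if H+
#: leaves the cell). Stromal pathways are positive INTO the cell internally,
#: hence the -1.
_REPORT_ROWS = (
    ("stromal", "nkcc", Species.NA, -1.0),
    ("stromal", "aes", Species.HCO3, -1.0),
    ("stromal", "nhe", Species.H, -1.0),
    ("stromal", "nbcs", Species.NA, -1.0),
    ("stromal", "k_channel", Species.K, -1.0),
    ("pc", "pump", Species.NA, 1.0),
    ("pc", "aep", Species.HCO3, 1.0),
    ("pc", "nbcp", Species.NA, 1.0),
    ("pc", "k_channel", Species.K, 1.0),
    ("pc", "cl_channel", Species.CL, 1.0),
)


def flux_breakdown_report(result: ExperimentResult) -> pd.DataFrame:
    """Per-pathway carrier fluxes in the out-of-the-cell sign convention.

    One row per transporter/channel: the flux (mol/s) of the pathway's lead
    species, positive when directed out of the cell (HCO3- out for the anion
    exchangers, H+ out for nhe), for the reference and, when present, the
    perturbed solution.
    """

    def column(sol: SteadyStateSolution) -> list[float]:
        vals = []
        for membrane, pathway, species, sign in _REPORT_ROWS:
            vals.append(sign * getattr(sol.fluxes, membrane)[pathway][species])
        return vals

    data = {"reference": column(result.reference)}
    if result.perturbed is not None:
        data["perturbed"] = column(result.perturbed)
    index = [pathway if membrane == "stromal" else pathway.replace("k_channel", "k_channel_pc")
             for membrane, pathway, _s, _sign in _REPORT_ROWS]
    # disambiguate the two K+ channels
    index[4] = "k_channel_s"
    return pd.DataFrame(data, index=index)


def peclet_number(velocity: float, length: float, diffusivity: float) -> float:
    """Péclet number U H / D: advective vs diffusive solute export from the PC.

    Any consistent unit system; all arguments must be positive (velocity may
    be zero, giving Pe = 0).
    """
    if velocity < 0 or length <= 0 or diffusivity <= 0:
        raise ValueError("require velocity >= 0, length > 0, diffusivity > 0")
    return velocity * length / diffusivity
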