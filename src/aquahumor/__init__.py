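"""aquahumor: compartmental model of aqueous humor production.

Predicts the aqueous humor production rate, posterior-chamber composition and
transepithelial potential of the ciliary epithelium from stromal boundary
concentrations and the membrane distribution of ion channels, transporters and
the Na+/K+ pump.
"""

from .constants import FARADAY, R_GAS, Species, VALENCES
from .experiments import (
    ExperimentResult,
    PerturbationSpec,
    flux_breakdown_report,
    inhibit_ca,
    peclet_number,
    run_baseline,
    scale_parameter,
)
from .parameters import SENSITIVITY_PARAMETERS, ModelParameters
from .sensitivity import (
    PairedEnsembleSummary,
    SensitivityConfig,
    SensitivityResult,
    efast_design,
    efast_total_index,
    paired_ca_comparison,
    run_sensitivity,
)
from .solver import (
    ConvergenceError,
    SolverConfig,
    SteadyStateSolution,
    assess_stability,
    integrate_transient,
    solve_steady_state,
)
from .state import CompartmentState, make_stroma
from .system import residual_system

__version__ = "0.1.0"

__all__ = [
    "CompartmentState",
    "ConvergenceError",
    "ExperimentResult",
    "FARADAY",
    "ModelParameters",
    "PairedEnsembleSummary",
    "PerturbationSpec",
    "R_GAS",
    "SENSITIVITY_PARAMETERS",
    "SensitivityConfig",
    "SensitivityResult",
    "SolverConfig",
    "Species",
    "SteadyStateSolution",
    "VALENCES",
    "assess_stability",
    "efast_design",
    "efast_total_index",
    "flux_breakdown_report",
    "inhibit_ca",
    "integrate_transient",
    "make_stroma",
    "paired_ca_comparison",
    "peclet_number",
    "residual_system",
    "run_baseline",
    "run_sensitivity",
    "scale_parameter",
    "solve_steady_state",
]


def load_config(path=None):
    """Load a model configuration (see :mod:`aquahumor.config`)."""
    from .config import load_config as _load

    return _load(path)
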