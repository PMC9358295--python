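import numpy as np
import pytest

from aquahumor.config import load_config
from aquahumor.solver import SolverConfig, solve_steady_state


@pytest.fixture(scope="session")
def config():
    """(params, stroma, solver_config, sensitivity_config) from the shipped file."""
    return load_config()


@pytest.fixture(scope="session")
def params(config):
    return config[0]


@pytest.fixture(scope="session")
def stroma(config):
    return config[1]


@pytest.fixture(scope="session")
def baseline_solution(params, stroma):
    """Baseline steady state, solved once per session."""
    return solve_steady_state(params, stroma, SolverConfig())


@pytest.fixture(scope="session")
def noca_solution(params, stroma, baseline_solution):
    """Steady state with carbonic anhydrase inhibited (k_d, k_h / 1e6)."""
    return solve_steady_state(
        params.without_ca(), stroma, SolverConfig(), initial_guess=baseline_solution.unknowns
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20220801)
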