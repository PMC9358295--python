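"""Steady-state root solving and transient (DAE) relaxation of the model.

The steady state is found with a damped quasi-Newton root solve (scipy hybr)
on the nondimensionalized 18-equation system, with a physiological initial
guess and a seeded log-uniform multistart fallback. Stability is verified, as
an independent numerical device, by time-marching the solute balances with the
electric potentials enforced as algebraic zero-net-current constraints.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .constants import N_SPECIES, VALENCES, Species
from .fluxes import ConcentrationClampWarning, MembraneFluxes, assemble_membrane_fluxes, water_flux
from .parameters import ModelParameters
from .reactions import reaction_rates, split_carbonate_totals
from .state import CompartmentState, h_conc_from_ph
from .system import (
    N_UNKNOWNS,
    RESIDUAL_SCALE,
    UNKNOWN_SCALE,
    compartment_volumes,
    membrane_currents,
    pack_unknowns,
    residual_system,
    unpack_unknowns,
)


@dataclass
class SolverConfig:
    """Settings for the steady-state root solve."""

    tolerance: float = 1e-9          # max |scaled residual| accepted as converged
    max_iterations: int = 400        # per root attempt (scipy maxfev multiplier)
    multistart: int = 20             # random restarts after the physiological guess
    multistart_spread: float = 0.7   # log-uniform half-width (natural log units)
    seed: int = 1234                 # RNG seed for multistart draws
    negative_conc_tol: float = -1e-10  # most negative concentration tolerated (mM)

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class SteadyStateSolution:
    """A converged root of the steady-state system with diagnostics."""

    cell: CompartmentState
    pc: CompartmentState
    water_flux: float                # Q (m^3/s)
    residual_norm: float             # max |scaled residual|
    fluxes: MembraneFluxes
    params: ModelParameters
    stroma: CompartmentState
    n_evaluations: int = 0
    guess_source: str = "physiological"

    @property
    def unknowns(self) -> np.ndarray:
        return pack_unknowns(self.cell, self.pc, self.water_flux)

    def currents(self) -> dict[str, float]:
        """Net electric current across each membrane (mol-charge/s)."""
        return membrane_currents(self.fluxes)

    def transepithelial_ion_fluxes(self) -> np.ndarray:
        """Total solute flux into the PC per unit epithelial area (umol/m^2/s)."""
        total = self.fluxes.total("pc") + self.fluxes.total("tj")
        return total / self.params.area_s * 1e6


class ConvergenceError(RuntimeError):
    """Raised when no admissible root is found; carries the best residual."""

    def __init__(self, message: str, best_residual: float):
        super().__init__(f"{message} (best residual {best_residual:.3e})")
        self.best_residual = best_residual


def physiological_guess(params: ModelParameters, stroma: CompartmentState) -> np.ndarray:
    """Initial unknown vector built from experimentally measured concentrations.

    Cell Na 15, K 162, Cl 46 mM and V = -70 mV; PC Na 152, K 3.9, Cl 131,
    HCO3 22 mM and V = -1 mV; both at pH 7.4 with the carbonate minors set by
    the buffer equilibria; C_X from cell electroneutrality; Q = 3e-11 m^3/s.
    """
    h = h_conc_from_ph(7.4)

    def carbonates(hco3: float) -> tuple[float, float]:
        h2co3 = params.kd_assoc * h * hco3
        co2 = params.k_dehyd / params.k_hyd * h2co3
        return co2, h2co3

    co2_c, h2co3_c = carbonates(26.0)
    cell = CompartmentState(
        conc=np.array([15.0, 162.0, 46.0, 26.0, h, co2_c, h2co3_c]),
        potential=-0.070,
        z_fixed=params.z_fixed,
    )
    cell.c_fixed = -(VALENCES @ cell.conc) / params.z_fixed
    co2_p, h2co3_p = carbonates(22.0)
    pc = CompartmentState(
        conc=np.array([152.0, 3.9, 131.0, 22.0, h, co2_p, h2co3_p]), potential=-0.001
    )
    # PC electroneutrality for the guess: absorb the tiny imbalance into Cl-
    pc.conc[Species.CL] += VALENCES @ pc.conc
    return pack_unknowns(cell, pc, 3e-11)


def _scaled_residual(
    x: np.ndarray, params: ModelParameters, stroma: CompartmentState
) -> np.ndarray:
    u = x * UNKNOWN_SCALE
    return residual_system(u, params, stroma) / RESIDUAL_SCALE


def solve_steady_state(
    params: ModelParameters,
    stroma: CompartmentState,
    config: SolverConfig | None = None,
    initial_guess: np.ndarray | None = None,
) -> SteadyStateSolution:
    """Solve the 18 nonlinear steady-state equations.

    Tries the supplied guess (or the physiological one), then seeded
    log-uniform multistart around it. A root is admissible only if all
    concentrations are non-negative at convergence; tiny negative roundoff
    below ``config.negative_conc_tol`` is clipped.

    Raises
    ------
    ConvergenceError
        If no admissible root is found within the multistart budget.
    """
    config = config or SolverConfig()
    base_guess = (
        np.asarray(initial_guess, dtype=float)
        if initial_guess is not None
        else physiological_guess(params, stroma)
    )
    rng = np.random.default_rng(config.seed)
    best_residual = np.inf
    n_evals = 0
    attempts: list[tuple[np.ndarray, str]] = [(base_guess, "physiological" if initial_guess is None else "user")]

    for attempt in range(config.multistart + 1):
        if attempt > 0:
            draw = base_guess.copy()
            # log-uniform jitter of the positive unknowns, additive for potentials
            draw[:15] *= np.exp(rng.uniform(-config.multistart_spread, config.multistart_spread, 15))
            draw[16:] += rng.uniform(-0.02, 0.02, 2)
            attempts.append((draw, f"multistart-{attempt}"))
        guess, source = attempts[-1]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConcentrationClampWarning)
                sol = root(
                    _scaled_residual,
                    guess / UNKNOWN_SCALE,
                    args=(params, stroma),
                    method="hybr",
                    options={"maxfev": config.max_iterations * (N_UNKNOWNS + 1), "xtol": 1e-12},
                )
                res_norm = float(np.max(np.abs(_scaled_residual(sol.x, params, stroma))))
        except FloatingPointError:
            continue  # iterate left the admissible region; try another start
        n_evals += sol.nfev
        best_residual = min(best_residual, res_norm)
        if res_norm >= config.tolerance:
            continue
        u = sol.x * UNKNOWN_SCALE
        conc = np.concatenate([u[:14], u[14:15]])
        if conc.min() < config.negative_conc_tol:
            continue  # converged to an unphysical root; retry
        u[:15] = np.clip(u[:15], 0.0, None)
        cell, pc, q = unpack_unknowns(u, params.z_fixed)
        fluxes = assemble_membrane_fluxes(params, stroma, cell, pc)
        return SteadyStateSolution(
            cell=cell,
            pc=pc,
            water_flux=q,
            residual_norm=res_norm,
            fluxes=fluxes,
            params=params,
            stroma=stroma,
            n_evaluations=n_evals,
            guess_source=source,
        )
    raise ConvergenceError(
        f"steady-state solve failed after {config.multistart + 1} starts", best_residual
    )


# ---------------------------------------------------------------------------
# transient relaxation (numerical stability check)
# ---------------------------------------------------------------------------

_TRANSIENT_IDX = {
    "na": 0, "k": 1, "cl": 2, "b_hco3": 3, "b_h": 4, "co2": 5,
}


def _states_from_transient(
    y: np.ndarray, params: ModelParameters, c_fixed: float, potentials: np.ndarray
) -> tuple[CompartmentState, CompartmentState]:
    """Rebuild full compartment states from the 12 transient invariants."""
    states = []
    for block, (c_x, v) in zip((y[:6], y[6:]), ((c_fixed, potentials[0]), (0.0, potentials[1]))):
        hco3, h, h2co3 = split_carbonate_totals(block[3], block[4], params.kd_assoc)
        conc = np.array([block[0], block[1], block[2], hco3, h, block[5], h2co3])
        states.append(
            CompartmentState(conc=conc, potential=v, c_fixed=c_x, z_fixed=params.z_fixed)
        )
    return states[0], states[1]


def _transient_from_states(cell: CompartmentState, pc: CompartmentState) -> np.ndarray:
    out = np.empty(12)
    for i, s in enumerate((cell, pc)):
        c = s.conc
        out[6 * i : 6 * i + 6] = [
            c[Species.NA], c[Species.K], c[Species.CL],
            c[Species.HCO3] + c[Species.H2CO3],
            c[Species.H] + c[Species.H2CO3],
            c[Species.CO2],
        ]
    return out


@dataclass
class TransientResult:
    """Trajectory of a transient relaxation run."""

    times: np.ndarray                 # s
    states: np.ndarray                # (n_times, 12) invariant matrix
    potentials: np.ndarray            # (n_times, 2) V^c, V^p (volts)
    water_flux: np.ndarray            # (n_times,) Q (m^3/s)
    c_fixed: float
    success: bool
    message: str = ""

    def final_states(self, params: ModelParameters) -> tuple[CompartmentState, CompartmentState]:
        return _states_from_transient(self.states[-1], params, self.c_fixed, self.potentials[-1])


def integrate_transient(
    params: ModelParameters,
    stroma: CompartmentState,
    initial_cell: CompartmentState,
    initial_pc: CompartmentState,
    horizon: float,
    n_save: int = 50,
    rtol: float = 1e-8,
) -> TransientResult:
    """Time-march the solute balances toward steady state.

    Differential variables are the twelve fast-reaction invariants (Na+, K+,
    Cl-, HCO3-+H2CO3, H++H2CO3, CO2 in cell and PC); the potentials are
    algebraic unknowns enforcing zero net current across the cell boundary and
    into the PC at every instant, which keeps both compartments electroneutral.
    The fixed-charge concentration C_X is a constant of the motion (set from
    the initial cell state). Compartment volumes come from the geometry:
    A^s~ L for the cell and A^PC H for the PC.
    """
    vol_cell, vol_pc = compartment_volumes(params)
    c_fixed = initial_cell.c_fixed
    v_guess = np.array([initial_cell.potential, initial_pc.potential])
    y0 = _transient_from_states(initial_cell, initial_pc)
    last_v = {"v": v_guess.copy()}

    def solve_potentials(y: np.ndarray) -> tuple[np.ndarray, CompartmentState, CompartmentState, MembraneFluxes, float]:
        def current_residual(v: np.ndarray) -> np.ndarray:
            cell, pc = _states_from_transient(y, params, c_fixed, v)
            fx = assemble_membrane_fluxes(params, stroma, cell, pc)
            q_cp = water_flux(params.k_water_p, params.sigma, params.area_p, cell, pc, params.temperature)
            q_sp = water_flux(params.k_water_tj, params.sigma, params.area_tj, stroma, pc, params.temperature)
            q = q_cp + q_sp
            j_sc, j_cp, j_sp = fx.total("stromal"), fx.total("pc"), fx.total("tj")
            i_cell = VALENCES @ (j_sc - j_cp)
            i_pc = VALENCES @ (j_cp + j_sp - q * pc.conc)
            return np.array([i_cell, i_pc]) / 3.6e-9

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConcentrationClampWarning)
            sol = root(current_residual, last_v["v"], method="hybr", options={"xtol": 1e-13})
        if not sol.success and np.max(np.abs(sol.fun)) > 1e-7:
            raise FloatingPointError("zero-current potential solve failed")
        last_v["v"] = sol.x
        cell, pc = _states_from_transient(y, params, c_fixed, sol.x)
        fx = assemble_membrane_fluxes(params, stroma, cell, pc)
        q_cp = water_flux(params.k_water_p, params.sigma, params.area_p, cell, pc, params.temperature)
        q_sp = water_flux(params.k_water_tj, params.sigma, params.area_tj, stroma, pc, params.temperature)
        return sol.x, cell, pc, fx, q_cp + q_sp

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        _v, cell, pc, fx, q = solve_potentials(y)
        r_cell = reaction_rates(cell, params.k_dehyd, params.k_hyd, params.kd_assoc).rates
        r_pc = reaction_rates(pc, params.k_dehyd, params.k_hyd, params.kd_assoc).rates
        net_cell = (fx.total("stromal") - fx.total("pc")) / vol_cell + r_cell
        net_pc = (fx.total("pc") + fx.total("tj") - q * pc.conc) / vol_pc + r_pc
        dy = np.empty(12)
        for i, net in enumerate((net_cell, net_pc)):
            dy[6 * i : 6 * i + 6] = [
                net[Species.NA], net[Species.K], net[Species.CL],
                net[Species.HCO3] + net[Species.H2CO3],
                net[Species.H] + net[Species.H2CO3],
                net[Species.CO2],
            ]
        return dy

    atol = np.concatenate([np.abs(y0[:6]), np.abs(y0[6:])]) * 1e-10 + 1e-14
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConcentrationClampWarning)
        ivp = solve_ivp(
            rhs,
            (0.0, horizon),
            y0,
            method="BDF",
            t_eval=np.linspace(0.0, horizon, n_save),
            rtol=rtol,
            atol=atol,
        )
    potentials = np.empty((len(ivp.t), 2))
    qs = np.empty(len(ivp.t))
    for i, y in enumerate(ivp.y.T):
        v, _cell, _pc, _fx, q = solve_potentials(y)
        potentials[i] = v
        qs[i] = q
    return TransientResult(
        times=ivp.t,
        states=ivp.y.T.copy(),
        potentials=potentials,
        water_flux=qs,
        c_fixed=c_fixed,
        success=ivp.success,
        message=ivp.message if not ivp.success else "",
    )


@dataclass
class StabilityVerdict:
    """Outcome of perturb-and-relax stability testing of a steady state."""

    stable: bool
    max_return_distance: float        # worst final relative distance to the root
    distances: list[float] = field(default_factory=list)


def assess_stability(
    params: ModelParameters,
    stroma: CompartmentState,
    solution: SteadyStateSolution,
    n_perturbations: int = 3,
    magnitude: float = 0.05,
    seed: int = 0,
    horizon: float = 2e4,
    return_tol: float = 1e-3,
) -> StabilityVerdict:
    """Perturb the converged concentrations and check relaxation back to the root.

    Each trial multiplies every solute concentration by (1 +/- ``magnitude``)
    with seeded random signs, integrates the transient model over ``horizon``
    seconds, and measures the final relative distance (per component, against
    the steady-state invariants). Stable iff all trials return within
    ``return_tol``. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    y_ref = _transient_from_states(solution.cell, solution.pc)
    distances = []
    for _ in range(max(n_perturbations, 1)):
        cell = solution.cell.copy()
        pc = solution.pc.copy()
        if magnitude > 0:
            cell.conc = cell.conc * (1.0 + magnitude * rng.choice([-1.0, 1.0], N_SPECIES))
            pc.conc = pc.conc * (1.0 + magnitude * rng.choice([-1.0, 1.0], N_SPECIES))
            # compartment charge is a constant of the transient motion, so
            # restore electroneutrality via Cl- to keep the root reachable
            cell.conc[Species.CL] += cell.charge_concentration()
            pc.conc[Species.CL] += pc.charge_concentration()
        traj = integrate_transient(params, stroma, cell, pc, horizon=horizon, n_save=5)
        if not traj.success:
            distances.append(np.inf)
            continue
        rel = np.abs(traj.states[-1] - y_ref) / np.maximum(np.abs(y_ref), 1e-12)
        distances.append(float(rel.max()))
    worst = max(distances)
    return StabilityVerdict(stable=worst < return_tol, max_return_distance=worst, distances=distances)
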