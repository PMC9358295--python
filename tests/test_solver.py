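"""Steady-state solver and transient stability checks."""
import numpy as np
import pytest

from aquahumor.constants import Species
from aquahumor.solver import (
    SolverConfig,
    assess_stability,
    integrate_transient,
    physiological_guess,
    solve_steady_state,
)
from aquahumor.system import unpack_unknowns


def test_converged_solution_is_admissible(baseline_solution):
    sol = baseline_solution
    assert sol.residual_norm < 1e-9
    assert np.all(sol.cell.conc >= 0)
    assert np.all(sol.pc.conc >= 0)
    assert sol.cell.c_fixed > 0
    assert sol.water_flux > 0


def test_root_polishing_idempotent(params, stroma, baseline_solution):
    """Re-solving from the converged root returns it essentially unchanged."""
    again = solve_steady_state(
        params, stroma, SolverConfig(), initial_guess=baseline_solution.unknowns
    )
    ref = baseline_solution.unknowns
    assert np.allclose(again.unknowns, ref, rtol=1e-8, atol=1e-30)


def test_deterministic_given_seed(params, stroma):
    a = solve_steady_state(params, stroma, SolverConfig(seed=7))
    b = solve_steady_state(params, stroma, SolverConfig(seed=7))
    assert np.array_equal(a.unknowns, b.unknowns)


def test_solver_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(tolerance=0.0)
    with pytest.raises(ValueError):
        SolverConfig(max_iterations=0)


def test_monotone_in_pump_intensity(params, stroma, baseline_solution):
    """The production rate increases with pump intensity over 0.5-1.5x."""
    qs = []
    warm = baseline_solution.unknowns
    for factor in (0.5, 0.75, 1.0, 1.25, 1.5):
        sol = solve_steady_state(
            params.with_scaled(p_pump=factor), stroma, SolverConfig(), initial_guess=warm
        )
        warm = sol.unknowns
        qs.append(sol.water_flux)
    assert np.all(np.diff(qs) > 0)


class TestTransient:
    def test_fixed_point_stays(self, params, stroma, baseline_solution):
        """Initialized at the steady state, the trajectory stays on it."""
        sol = baseline_solution
        traj = integrate_transient(params, stroma, sol.cell, sol.pc, horizon=2e3, n_save=4)
        assert traj.success
        cell_t, pc_t = traj.final_states(params)
        assert np.allclose(cell_t.conc, sol.cell.conc, rtol=1e-5)
        assert np.allclose(pc_t.conc, sol.pc.conc, rtol=1e-5)

    def test_relaxes_to_algebraic_root(self, params, stroma, baseline_solution):
        """Starting from experimentally based concentrations, the transient
        converges to the same steady state as the algebraic solve."""
        sol = baseline_solution
        cell0, pc0, _ = unpack_unknowns(physiological_guess(params, stroma), params.z_fixed)
        # charge in each compartment is conserved by the dynamics; align the
        # invariants with the root so it is reachable
        cell0.c_fixed = sol.cell.c_fixed
        cell0.conc[Species.CL] += cell0.charge_concentration()
        pc0.conc[Species.CL] += pc0.charge_concentration()
        traj = integrate_transient(params, stroma, cell0, pc0, horizon=6e4, n_save=4)
        assert traj.success
        cell_t, pc_t = traj.final_states(params)
        assert np.allclose(cell_t.conc, sol.cell.conc, rtol=2e-3)
        assert np.allclose(pc_t.conc, sol.pc.conc, rtol=2e-3)
        assert traj.water_flux[-1] == pytest.approx(sol.water_flux, rel=5e-3)
        # electroneutrality holds along the whole trajectory
        for y, v in zip(traj.states, traj.potentials):
            from aquahumor.solver import _states_from_transient

            c, p = _states_from_transient(y, params, traj.c_fixed, v)
            assert abs(c.charge_concentration()) < 1e-6
            assert abs(p.charge_concentration()) < 1e-6

    def test_stability_zero_magnitude_trivial(self, params, stroma, baseline_solution):
        verdict = assess_stability(
            params, stroma, baseline_solution, n_perturbations=1, magnitude=0.0,
            seed=0, horizon=1e3,
        )
        assert verdict.stable
        assert verdict.max_return_distance < 1e-4

    def test_stable_under_5pct_perturbations_and_deterministic(
        self, params, stroma, baseline_solution
    ):
        kw = dict(n_perturbations=2, magnitude=0.05, seed=11, horizon=6e4)
        verdict = assess_stability(params, stroma, baseline_solution, **kw)
        assert verdict.stable
        repeat = assess_stability(params, stroma, baseline_solution, **kw)
        assert repeat.distances == verdict.distances
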