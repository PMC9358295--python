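"""Verify the steady state is a stable attractor by transient relaxation.

The solute balances are time-marched with the potentials enforced as
zero-net-current algebraic constraints; each trial perturbs the converged
concentrations by +/-5% (charge-preserving) and checks the trajectory returns
to the algebraic root.
"""
from aquahumor import assess_stability, load_config, solve_steady_state

params, stroma, solver_cfg, _ = load_config()
sol = solve_steady_state(params, stroma, solver_cfg)
verdict = assess_stability(
    params, stroma, sol, n_perturbations=3, magnitude=0.05, seed=0, horizon=6e4
)

print(f"stable: {verdict.stable}")
print(f"worst final relative distance to the root: {verdict.max_return_distance:.2e}")
print("Each trial relaxes the perturbed state over ~17 h of model time; a "
      "distance well below 1e-3 means the root is recovered.")
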