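"""Na+/K+-ATPase knockdown: halve the pump intensity and re-solve.

Demonstrates the generic parameter-scaling driver and the classic ouabain-like
response: intracellular Na+ rises, intracellular K+ falls, and the aqueous
production rate drops by roughly a quarter.
"""
from aquahumor import PerturbationSpec, load_config, scale_parameter

params, stroma, solver_cfg, _ = load_config()
result = scale_parameter(
    params, stroma, PerturbationSpec(factors={"p_pump": 0.5}), solver_cfg
)

print(f"Q change with pump at 50%: {result.delta_q_percent:+.1f}%")
changes = result.concentration_changes()
print(f"cell Na+: {result.reference.cell.conc[0]:.1f} -> "
      f"{result.perturbed.cell.conc[0]:.1f} mM ({changes.loc['Na+', 'cell']:+.1f})")
print(f"cell K+ : {result.reference.cell.conc[1]:.1f} -> "
      f"{result.perturbed.cell.conc[1]:.1f} mM ({changes.loc['K+', 'cell']:+.1f})")
print("Reduced active Na+ extrusion dissipates the cation gradients that "
      "drive osmotic water secretion into the posterior chamber.")
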