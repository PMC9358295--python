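# Methods

## Model structure and assumptions

The ciliary epithelium is treated as a single well-mixed cellular compartment
between a fixed stromal boundary and the posterior chamber (PC), with the
tight junction as a third, paracellular path directly connecting stroma and
PC. The model is zero-dimensional and steady-state: all spatial structure
inside a compartment — in particular standing-gradient (local) osmosis in the
lateral clefts — is neglected, and cell volume is not a state variable.
Water moves by osmosis only; the hydrostatic and oncotic pressure
contributions of the full Starling relation are taken to cancel and are
omitted (`σ = 1` for ions, ideal semipermeable membranes). Solute export from
the PC is purely advective (`Q C_i^p`): the Péclet number of the iris–lens
channel, `Pe = UH/D ≈ 600` for U = 0.2 mm/s, H = 6 mm, D = 2·10⁻³ mm²/s,
makes diffusive export negligible.

Seven species are tracked (Na⁺, K⁺, Cl⁻, HCO₃⁻, H⁺, CO₂, H₂CO₃; valences
+1, +1, −1, −1, +1, 0, 0) plus a non-diffusible intracellular fixed charge X
with valence −1.5 whose concentration is an unknown of the steady-state
problem. Unknowns (18): 7 + 7 concentrations, `C_X`, `Q`, `V^c`, `V^p`;
equations: 7 + 7 solute balances (with the buffer reduction below), two water
balances (`Q^{sc} = Q^{cp}`, `Q = Q^{cp} + Q^{sp}`) and electroneutrality of
cell and PC.

## Flux laws

The membrane distribution of pathways is: stromal membrane — nkcc
(Na⁺/K⁺/2Cl⁻), aes (Cl⁻/HCO₃⁻ exchange), nhe (Na⁺/H⁺ exchange), nbcs
(Na⁺/2HCO₃⁻), K⁺ channel; PC membrane — Na⁺/K⁺-ATPase, aep, nbcp, K⁺ and Cl⁻
channels; tight junction — electrodiffusion of Na⁺, K⁺, Cl⁻, HCO₃⁻ with a
common permeability. CO₂ and H₂CO₃ cross everything by simple diffusion.

The kinetic forms are the package's own design choices, selected as the
standard shapes used in epithelial transport modeling:

- **Channels / tight junction**: GHK constant-field flux. The removable
  singularity at ΔV = 0 is handled by a first-order series below
  |φ| < 10⁻¹⁰, and the expression is rewritten with non-positive exponents on
  each sign branch so extreme potentials cannot overflow. The GHK flux is
  verified in the tests against an independent shooting solution of the 1-D
  constant-field Nernst–Planck boundary-value problem.
- **Electroneutral coupled transporters** (nkcc, aes/aep, nhe): flux
  proportional to the log mass-action quotient of the full translocated
  stoichiometry, e.g. `ln[(Na_s K_s Cl_s²)/(Na_c K_c Cl_c²)]` for nkcc. This
  is linear nonequilibrium thermodynamics: flux ∝ affinity, vanishing exactly
  at transporter equilibrium, antisymmetric under side swap.
- **nbc** (1 Na⁺ : 2 HCO₃⁻, net carrier charge −1): same log quotient plus
  the electrical term `−FΔV/RT`.
- **Pump**: saturable Strieter–Weinstein kinetics,
  `J_Na = 3 A P_pump [Na_c/(Na_c+K_Na)]³ [K_p/(K_p+K_K)]²` with
  `K_Na = 0.2(1 + K_c/8.33) mM` and `K_K = 0.1(1 + Na_p/18.5) mM`, the
  classical half-saturation constants with trans-side competition.

Sign convention: all internal fluxes are positive in the secretion direction
(stroma→cell, cell→PC, stroma→PC); the reporting layer flips to the
"positive out of the cell" convention used in the flux-breakdown tables.

## Carbonate buffer reduction

`HCO₃⁻ + H⁺ ⇌ H₂CO₃` is effectively instantaneous, so it is never evaluated
kinetically. Each reacting compartment instead balances the fast-reaction
invariants `HCO₃⁻ + H₂CO₃` and `H⁺ + H₂CO₃` and imposes
`C_H2CO3 = K_d C_H C_HCO3` (K_d = 5.3 mM⁻¹, association constant) as an
algebraic constraint. The slow step contributes
`R = k_d C_H2CO3 − k_h C_CO2` (k_d = 4.96·10⁵ s⁻¹, k_h = 1.45·10³ s⁻¹
CA-catalysed; both ÷10⁶ under CA inhibition) scaled by the compartment volume
(cell `A^s̃ L = 6·10⁻⁹ m³`, PC `A^PC H = 1.56·10⁻⁷ m³`). When recovering
(HCO₃⁻, H⁺, H₂CO₃) from the invariants, the quadratic is solved with the
cancellation-safe root formula; the (H⁺ + H₂CO₃) pairing keeps full relative
precision in H⁺ (~3·10⁻⁸ mM against ~5·10⁻³ mM totals), which the naive
(H⁺ − HCO₃⁻) pairing would destroy.

The stromal boundary is made reaction-consistent at load: H⁺ from pH 7.42,
H₂CO₃ from the fast equilibrium, CO₂ from the slow-step equilibrium
(≈ 1.72 mM). Electroneutrality of the imposed boundary is enforced exactly by
absorbing the ~4·10⁻⁵ mM residual (the H⁺ itself, below print precision)
into Cl⁻.

## Parameters

All values are stored in SI; the configuration file uses the conventional
reporting units (transporter intensities ×10⁻⁶ mol m⁻² s⁻¹, channel
permeabilities ×10⁻⁸ m s⁻¹). The shipped baseline: geometry L = 10⁻⁵ m,
H = 6·10⁻³ m, A^s̃ = A^p̃ = 6·10⁻⁴ m², A^tj = 6·10⁻⁷ m², A^PC = 2.6·10⁻⁵ m²;
hydraulic conductivities K^s̃ = K^tj = 2·10⁻¹¹, K^p̃ = 2·10⁻¹⁰ m s⁻¹ Pa⁻¹;
CO₂/H₂CO₃ permeabilities 1.5·10⁻³ / 1.28·10⁻⁵ m s⁻¹ (stromal and tj) and
ten-fold higher on the PC membrane; intensities P_pump = 6, P_nkcc = 1,
P_aes = 4, P_aep = 0.4, P_nhe = 3.4; permeabilities P_K⁺^s̃ = 5,
P_K⁺^p̃ = 30, P_Cl⁻^p̃ = 6, P_tj = 600.

The two Na⁺/HCO₃⁻ cotransporter intensities have no published values; they
were calibrated once by least squares against the reference baseline steady
state (concentrations, potentials, fluxes, Q), giving **P_nbcs = 0.6** and
**P_nbcp = 0.98** (×10⁻⁶ mol m⁻² s⁻¹), recorded in the shipped configuration.
With these two numbers fixed, the CA-inhibited state, the knockdown responses
and the sensitivity ranking are all emergent predictions — nothing else was
fitted.

## Steady-state solver

The residual system is nondimensionalized before solving: each unknown is
scaled by a fixed per-species physiological reference (so H⁺ at 10⁻⁸ mM and
Na⁺ at 10² mM are equally well conditioned — a single common concentration
scale would leave the H⁺ column numerically invisible), solute balances by a
typical pump flux (3.6·10⁻⁹ mol/s), water balances by 3·10⁻¹¹ m³/s,
equilibrium constraints by 5·10⁻³ mM and electroneutrality by 1 mM. Roots are
found with scipy's Powell-hybrid method from a physiological guess assembled
from experimentally measured concentrations; if that fails, up to 20 seeded
log-uniform restarts around the guess are tried (default seed 1234).
Convergence requires max |scaled residual| < 10⁻⁹ and non-negative
concentrations; roots with negative concentrations are rejected and retried.
Ensemble drivers warm-start each solve from the previous design row (adjacent
rows lie close on the eFAST search curve) and fall back to the transformed
baseline solution plus 30 restarts; with this policy, 10⁴-member ensembles
complete without failures. Concentrations entering log quotients are clamped
at 10⁻¹² mM with an explicit warning (suppressed only inside solver
iterations, never at a returned solution).

## Transient formulation (stability check)

The time-dependent variant is a numerical device to verify that the algebraic
root is a stable attractor, mirroring the original two-pronged approach. The
differential state is the twelve fast-reaction invariants (Na⁺, K⁺, Cl⁻,
HCO₃⁻+H₂CO₃, H⁺+H₂CO₃, CO₂ in cell and PC) divided by the compartment
volumes above; the potentials are algebraic unknowns enforcing zero net
current across the cell boundary and into the PC at every instant
(DAE-style), which preserves compartment charge exactly; `C_X` is a constant
of the motion. Integration uses BDF with per-component absolute tolerances.
Perturb-and-relax trials multiply all concentrations by (1 ± 5%) with seeded
random signs, restore electroneutrality through Cl⁻ (charge is conserved by
the dynamics, so an unbalanced start could never return to the root), and
require the final relative distance to the root to fall below 10⁻³ over a
6·10⁴ s horizon (≈ 11 PC turnover times; the PC clearance time
`V_PC/Q ≈ 5.4·10³ s` is the slowest scale in the problem).

At steady state the membrane currents satisfy `I^{sc} = I^{cp}` and
`I^{cp} + I^{sp} = 0` — zero net current into each compartment — but the
individual membrane currents do not vanish: a loop current of ~1.3·10⁻¹⁰
mol-charge/s circulates through the cellular path and returns via the tight
junction, as expected for a leaky epithelium.

## Global sensitivity analysis

The eFAST estimator is implemented in the package (design + FFT analysis).
Each of the ten varied parameters (the pump intensity is held fixed) is in
turn driven at the high frequency `ω_max = (N_s − 1)/2M` along the search
curve `x = 1/2 + arcsin(sin(ω s + φ))/π`, with the complementary parameters
on low frequencies `floor(linspace(1, ω_max/2M, 9))`; with interference
factor M = 4 all complementary harmonics up to order M stay below ω_max/2, so
the total-order index is `S_T = 1 − V_low/V` from the power spectrum of the
centered outputs. Random phases φ give N_r independent resampled curves per
parameter whose indices are averaged. Failed solves (none at baseline ranges)
would be mean-imputed within their curve and excluded from direction
estimates; >5% warns, >25% aborts. Effect directions are the sign of the
Spearman rank correlation between a parameter and the output over that
parameter's own blocks (total indices are unsigned, so the direction is a
separate, documented construct; |ρ| < 0.1 is reported as indeterminate).

Scales: the full design uses N_s = 1991 × N_r = 3 = 5973 runs per parameter
(59,730 solves); the reduced scale used by the tests keeps the same N_r = 3
and shrinks N_s to 257. The estimator is validated against the closed-form
total-order indices of the Ishigami function and a null (dummy) parameter.
Known limitation: indices below ~0.1 carry estimator noise of a few
hundredths at reduced scale, so the 4th and 5th ranked parameters for Q
(nkcc ≈ 0.065 vs aes ≈ 0.05 by an independent Sobol–Jansen check) are near
the resolution limit of a 257-sample curve; the ensemble means (CA
inhibition, pump knockdown) average over all members and are insensitive to
this. Ensemble experiments (paired CA on/off comparison, pump knockdown at
half intensity) reuse the identical design and seed in both arms so the
contrast is paired member by member.

## Numerical and design choices, summarized

- Per-species reference scaling of unknowns (conditioning of H⁺).
- GHK singularity: series below |φ| < 10⁻¹⁰; overflow-safe branches.
- Log-quotient clamp at 10⁻¹² mM, warning, never silent.
- Negative concentrations tolerated during iteration, rejected at roots.
- Multistart: physiological guess first, then 20 log-uniform draws
  (half-width e^0.7), fixed seed.
- Transient volumes from geometry; potentials algebraic; `C_X` frozen.
- CA inhibition is a parameter transform (÷10⁶ of both rates), composable
  with any other perturbation. A second inhibition is *not* a no-op: the
  uncatalysed kinetics still contribute a few percent to Q.

## Limitations

The model omits blood-flow coupling, cleft-gap local osmosis, cell volume
regulation, protein buffering and any hydrostatic/oncotic pressure terms; it
predicts production rate only (no outflow, hence no intraocular pressure).
The transporter kinetic forms are standard shapes, not molecularly detailed
cycle models: quantities that depend on the exact kinetics far from baseline
(e.g. the precise factor by which the nhe flux collapses under CA inhibition)
are reliable in sign and order of magnitude only. The tests exercise the
shipped physiological configuration and ±50% neighborhoods of it; behaviour
at parameter extremes outside those ranges is unverified.
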