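# Baseline configuration of the aqueous humor production model.
# Intensities are in 1e-6 mol/m^2/s, channel permeabilities in 1e-8 m/s
# (the conventional reporting units); everything else is SI. Stromal
# concentrations are in mM, the stromal potential in mV.

geometry:            # [GP]
  L: 1.0e-5          # cell layer thickness (m)
  H: 6.0e-3          # posterior chamber length (m)
  A_s: 6.0e-4        # stromal membrane area (m^2)
  A_p: 6.0e-4        # PC membrane area (m^2)
  A_tj: 6.0e-7       # tight junction area (m^2)
  A_pc: 2.6e-5       # PC cross-sectional area (m^2)

water_permeability:  # [P-H2O] hydraulic conductivities (m/s/Pa)
  K_s: 2.0e-11
  K_tj: 2.0e-11
  K_p: 2.0e-10

gas_permeability:    # [P-C] CO2 / H2CO3 permeabilities (m/s); tj shares stromal
  P_co2_s: 1.5e-3
  P_co2_p: 1.5e-2
  P_h2co3_s: 1.28e-5
  P_h2co3_p: 1.28e-4

reaction_rates:      # [RR]
  k_d: 4.96e+5       # H2CO3 dehydration (1/s), CA-catalysed
  k_h: 1.45e+3       # CO2 hydration (1/s), CA-catalysed
  K_d: 5.3           # association constant of HCO3- + H+ <-> H2CO3 (1/mM)

other:               # [Other]
  T: 310.0           # temperature (K)
  sigma: 1.0         # osmotic reflection coefficient
  z_X: -1.5          # valence of cellular fixed charge

ion_transport:       # [P-ions]
  intensities:       # 1e-6 mol/m^2/s
    P_pump: 6.0
    P_nkcc: 1.0
    P_aes: 4.0
    P_aep: 0.4
    P_nbcp: 0.98     # calibrated against the baseline steady state
    P_nbcs: 0.6      # calibrated against the baseline steady state
    P_nhe: 3.4
  permeabilities:    # 1e-8 m/s
    P_K_s: 5.0
    P_K_p: 30.0
    P_Cl_p: 6.0
    P_tj: 600.0

pump_kinetics:       # half-saturation constants (mM)
  km_na: 0.2
  k_kc: 8.33
  km_k: 0.1
  k_nap: 18.5

stroma:              # imposed boundary condition
  Na: 150.0
  K: 5.0
  Cl: 130.0
  HCO3: 25.0
  pH: 7.42
  V_mV: 0.0

solver:
  tolerance: 1.0e-9
  max_iterations: 400
  multistart: 20
  seed: 1234

sensitivity:
  range_fraction: 0.5
  samples_per_curve: 1991
  resamples: 3
  interference: 4
  seed: 0
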