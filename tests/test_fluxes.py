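"""Flux-law unit and property tests: limits, stoichiometry, antisymmetry,
and agreement of the GHK channel flux with a numerical Nernst-Planck oracle."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import root_scalar

from aquahumor.constants import FARADAY, R_GAS, Species, VALENCES
from aquahumor.fluxes import (
    ConcentrationClampWarning,
    anion_exchanger_flux,
    assemble_membrane_fluxes,
    electrodiffusive_flux,
    nbc_flux,
    nhe_flux,
    nkcc_flux,
    pump_flux,
    uncharged_diffusive_flux,
    water_flux,
)
from aquahumor.state import CompartmentState

T_BODY = 310.0


def _state(conc, potential=0.0, c_fixed=0.0):
    return CompartmentState(conc=np.asarray(conc, float), potential=potential, c_fixed=c_fixed)


def _random_state(rng, potential_scale=0.08):
    return _state(rng.uniform(0.01, 160.0, 7), potential=rng.uniform(-1, 1) * potential_scale)


concs = st.floats(min_value=0.05, max_value=200.0)
potentials = st.floats(min_value=-0.09, max_value=0.09)


class TestGHK:
    def test_zero_at_equilibrium(self):
        a = _state([10] * 7)
        b = _state([10] * 7)
        assert electrodiffusive_flux(Species.NA, 1e-8, 1.0, a, b, T_BODY) == 0.0

    def test_zero_permeability(self, rng):
        a, b = _random_state(rng), _random_state(rng)
        assert electrodiffusive_flux(Species.K, 0.0, 1.0, a, b, T_BODY) == 0.0

    def test_negative_permeability_rejected(self):
        a = _state([10] * 7)
        with pytest.raises(ValueError):
            electrodiffusive_flux(Species.K, -1e-8, 1.0, a, a, T_BODY)

    def test_fickian_limit(self):
        """As dV -> 0 the GHK flux approaches P A (C_m - C_k)."""
        a = _state([2.0] * 7, potential=0.0)
        b = _state([1.0] * 7, potential=0.0)
        j = electrodiffusive_flux(Species.NA, 1e-8, 1.0, a, b, T_BODY)
        assert j == pytest.approx(1e-8 * 1.0 * 1.0, rel=1e-12)
        # approach through a sequence of shrinking potentials
        for dv in (1e-3, 1e-6, 1e-9):
            phi = FARADAY * dv / (R_GAS * T_BODY)
            a_dv = _state([2.0] * 7, potential=dv)
            j_dv = electrodiffusive_flux(Species.NA, 1e-8, 1.0, a_dv, b, T_BODY)
            series = 1e-8 * (1.0 + 0.5 * phi * 3.0)
            # first-order series: next correction is O(phi^2)
            assert j_dv == pytest.approx(series, rel=max(phi**2, 1e-6))

    def test_large_potentials_finite(self):
        """No overflow at potentials far outside the physiological range."""
        a = _state([10.0] * 7, potential=1.0)
        b = _state([1.0] * 7, potential=-1.0)
        for frm, to in ((a, b), (b, a)):
            j = electrodiffusive_flux(Species.CL, 1e-8, 1.0, frm, to, T_BODY)
            assert np.isfinite(j)

    @pytest.mark.parametrize("species", [Species.NA, Species.CL])
    def test_nernst_planck_oracle(self, species, rng):
        """GHK matches a shooting solution of the 1-D constant-field
        Nernst-Planck boundary-value problem on random parameter draws."""
        z = VALENCES[species]
        delta = 1e-8  # membrane thickness (m); P = D / delta
        for _ in range(10):
            cm, ck = rng.uniform(0.5, 150.0, 2)
            dv = rng.uniform(-0.09, 0.09)
            perm = 10 ** rng.uniform(-9, -7)
            diff = perm * delta
            efield = dv / delta  # V(x) linear from V_m to V_k

            def c_end(j_density):
                # dc/dx = (z F E / RT) c - j / D, c(0) = cm
                k = z * FARADAY * efield / (R_GAS * T_BODY)
                sol = solve_ivp(
                    lambda x, c: k * c - j_density / diff,
                    (0.0, delta), [cm], rtol=1e-12, atol=1e-14,
                )
                return sol.y[0, -1] - ck

            scale = perm * max(cm, ck) * 10
            bracket = root_scalar(c_end, bracket=[-1e3 * scale, 1e3 * scale], xtol=1e-30)
            j_oracle = bracket.root  # mol/m^2/s

            a = _state([cm] * 7, potential=dv)
            b = _state([ck] * 7, potential=0.0)
            j_ghk = electrodiffusive_flux(species, perm, 1.0, a, b, T_BODY)
            assert j_ghk == pytest.approx(j_oracle, rel=1e-6)


class TestDiffusiveAndWater:
    def test_zero_gradient(self):
        a = _state([5] * 7)
        assert uncharged_diffusive_flux(Species.CO2, 1e-2, 1.0, a, a) == 0.0

    def test_linearity_in_gradient(self):
        a, b = _state([3.0] * 7), _state([1.0] * 7)
        c = _state([5.0] * 7)
        j1 = uncharged_diffusive_flux(Species.CO2, 1.5e-2, 6e-4, a, b)
        j2 = uncharged_diffusive_flux(Species.CO2, 1.5e-2, 6e-4, c, b)
        assert j2 == pytest.approx(2 * j1)
        # unit bookkeeping: P = 1.5e-2 m/s, A = 6e-4 m^2, dC = 1 mM = 1 mol/m^3
        assert uncharged_diffusive_flux(
            Species.CO2, 1.5e-2, 6e-4, _state([2.0] * 7), _state([1.0] * 7)
        ) == pytest.approx(9e-6)

    def test_water_flux_zero_at_isotonicity(self):
        a = _state([10] * 7)
        b = _state([9] * 7, c_fixed=7.0)
        assert water_flux(2e-10, 1.0, 6e-4, a, b, T_BODY) == pytest.approx(0.0, abs=1e-25)

    def test_water_flux_toward_hyperosmotic_and_linear_in_k(self):
        lo, hi = _state([100] * 7), _state([110] * 7)
        q = water_flux(2e-10, 1.0, 6e-4, lo, hi, T_BODY)
        assert q > 0
        assert water_flux(4e-10, 1.0, 6e-4, lo, hi, T_BODY) == pytest.approx(2 * q)


class TestTransporters:
    @given(
        p=st.floats(min_value=1e-8, max_value=1e-5),
        ca=concs, cb=concs, kca=concs, kcb=concs, cla=concs, clb=concs,
    )
    @settings(max_examples=50, deadline=None)
    def test_nkcc_stoichiometry_and_antisymmetry(self, p, ca, cb, kca, kcb, cla, clb):
        a = _state([ca, kca, cla, 10, 1e-4, 1, 1e-2])
        b = _state([cb, kcb, clb, 10, 1e-4, 1, 1e-2])
        j_na, j_k, j_cl = nkcc_flux(p, 1.0, a, b)
        assert j_k == pytest.approx(j_na, rel=1e-12)
        assert j_cl == pytest.approx(2 * j_na, rel=1e-12)
        back = nkcc_flux(p, 1.0, b, a)
        assert back[0] == pytest.approx(-j_na, rel=1e-12, abs=1e-30)

    def test_nkcc_zero_at_equilibrium(self):
        a = _state([100, 10, 50, 10, 1e-4, 1, 1e-2])
        b = _state([50, 20, 50, 10, 1e-4, 1, 1e-2])  # product Na K Cl^2 equal
        j = nkcc_flux(1e-6, 1.0, a, b)
        assert j[0] == pytest.approx(0.0, abs=1e-18)

    @given(p=st.floats(min_value=1e-8, max_value=1e-5), c1=concs, c2=concs, c3=concs, c4=concs)
    @settings(max_examples=50, deadline=None)
    def test_anion_exchanger_electroneutral(self, p, c1, c2, c3, c4):
        a = _state([100, 5, c1, c2, 1e-4, 1, 1e-2])
        b = _state([100, 5, c3, c4, 1e-4, 1, 1e-2])
        j_cl, j_hco3 = anion_exchanger_flux(p, 1.0, a, b)
        assert j_cl + j_hco3 == pytest.approx(0.0, abs=1e-25)
        j2 = anion_exchanger_flux(2 * p, 1.0, a, b)
        assert j2[0] == pytest.approx(2 * j_cl, rel=1e-12, abs=1e-30)

    def test_anion_exchanger_zero_at_equilibrium(self):
        a = _state([100, 5, 60, 30, 1e-4, 1, 1e-2])
        b = _state([100, 5, 20, 10, 1e-4, 1, 1e-2])  # Cl/HCO3 ratios equal
        j_cl, _ = anion_exchanger_flux(1e-6, 1.0, a, b)
        assert j_cl == pytest.approx(0.0, abs=1e-18)

    @given(pna=concs, pnb=concs, ha=st.floats(1e-6, 1e-3), hb=st.floats(1e-6, 1e-3))
    @settings(max_examples=50, deadline=None)
    def test_nhe_coupling(self, pna, pnb, ha, hb):
        a = _state([pna, 5, 100, 25, ha, 1, 1e-2])
        b = _state([pnb, 5, 100, 25, hb, 1, 1e-2])
        j_na, j_h = nhe_flux(3.4e-6, 1.0, a, b)
        assert j_na == pytest.approx(-j_h, rel=1e-12, abs=1e-30)

    @given(
        na_a=concs, na_b=concs, ba=concs, bb=concs,
        va=potentials, vb=potentials,
    )
    @settings(max_examples=50, deadline=None)
    def test_nbc_stoichiometry_and_antisymmetry(self, na_a, na_b, ba, bb, va, vb):
        a = _state([na_a, 5, 100, ba, 1e-4, 1, 1e-2], potential=va)
        b = _state([na_b, 5, 100, bb, 1e-4, 1, 1e-2], potential=vb)
        j_na, j_hco3 = nbc_flux(1e-6, 1.0, a, b, T_BODY)
        assert j_hco3 == pytest.approx(2 * j_na, rel=1e-12, abs=1e-30)
        back = nbc_flux(1e-6, 1.0, b, a, T_BODY)
        assert back[0] == pytest.approx(-j_na, rel=1e-10, abs=1e-28)

    def test_pump_stoichiometry(self, params, rng):
        for _ in range(10):
            cell, pc = _random_state(rng), _random_state(rng)
            j_na, j_k = pump_flux(6e-6, 6e-4, cell, pc, params)
            assert j_na / j_k == pytest.approx(-3 / 2, rel=1e-12)
            assert j_na >= 0  # Na+ always extruded

    def test_pump_zero_intensity(self, params, rng):
        cell, pc = _random_state(rng), _random_state(rng)
        assert pump_flux(0.0, 6e-4, cell, pc, params) == (0.0, 0.0)

    def test_clamp_warning_on_zero_concentration(self):
        a = _state([0.0, 5, 100, 25, 1e-4, 1, 1e-2])
        b = _state([100, 5, 100, 25, 1e-4, 1, 1e-2])
        with pytest.warns(ConcentrationClampWarning, match="Na"):
            nkcc_flux(1e-6, 1.0, a, b)


class TestAssembly:
    def test_all_zero_intensities_give_zero_fluxes(self, params, stroma, rng):
        import dataclasses

        quiet = dataclasses.replace(
            params,
            **{
                name: 1e-300
                for name in (
                    "p_pump", "p_nkcc", "p_aes", "p_aep", "p_nbcp", "p_nbcs",
                    "p_nhe", "p_k_s", "p_k_p", "p_cl_p", "p_tj",
                    "p_co2_s", "p_co2_p", "p_h2co3_s", "p_h2co3_p",
                )
            },
        )
        cell = _random_state(rng)
        pc = _random_state(rng)
        fx = assemble_membrane_fluxes(quiet, stroma, cell, pc)
        for membrane in ("stromal", "pc", "tj"):
            assert np.allclose(fx.total(membrane), 0.0, atol=1e-290)

    def test_totals_are_sum_of_pathways(self, baseline_solution):
        fx = baseline_solution.fluxes
        for membrane in ("stromal", "pc", "tj"):
            pathways = getattr(fx, membrane)
            acc = sum(pathways.values())
            assert np.allclose(acc, fx.total(membrane), rtol=1e-14)

    def test_expected_pathway_placement(self, baseline_solution):
        fx = baseline_solution.fluxes
        assert set(fx.stromal) == {"nkcc", "aes", "nhe", "nbcs", "k_channel", "co2", "h2co3"}
        assert set(fx.pc) == {"pump", "aep", "nbcp", "k_channel", "cl_channel", "co2", "h2co3"}
        assert set(fx.tj) == {"electrodiffusion", "co2", "h2co3"}
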