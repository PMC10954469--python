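"""Core equilibrium model: van't Hoff constants, mass balance, partition
function, species fractions and heat capacity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_unfolded_root
from hnsemble.core_thermo import (
    R,
    DegenerateStateError,
    InvalidParameterError,
    ThermoParams,
    enthalpy_from_two_points,
    heat_capacity_curve,
    local_maxima,
    partition_terms,
    preset,
    solve_mass_balance,
    species_fractions,
    vant_hoff_K,
)


class TestVantHoff:
    def test_identity_at_reference_temperature(self):
        assert vant_hoff_K(2e6, -3.7e5, 298.15, 298.15) == pytest.approx(2e6, rel=1e-12)

    def test_athermal_equilibrium_is_temperature_independent(self):
        T = np.array([260.0, 298.15, 360.0])
        np.testing.assert_allclose(vant_hoff_K(5.0, 0.0, 298.15, T), 5.0)

    def test_dimerization_anchors_give_printed_enthalpy(self):
        # two-point inversion of K_D = 500 nM at 25 C and 8 uM at 37 C
        dH = enthalpy_from_two_points(2e6, 298.15, 1.25e5, 310.15)
        assert dH == pytest.approx(-1.776e5, rel=1e-3)
        assert vant_hoff_K(2e6, dH, 298.15, 310.15) == pytest.approx(1.25e5, rel=1e-9)

    @pytest.mark.parametrize("bad", [dict(T=-1.0), dict(T_ref=0.0), dict(K_ref=-2.0)])
    def test_invalid_inputs_raise(self, bad):
        kwargs = dict(K_ref=1e3, dH=1e4, T_ref=300.0, T=310.0)
        kwargs.update(bad)
        with pytest.raises(InvalidParameterError):
            vant_hoff_K(**kwargs)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        logK1=st.floats(-6, 9),
        logK2=st.floats(-6, 9),
        T1=st.floats(260, 350),
        dT=st.floats(5, 60),
    )
    def test_two_point_round_trip_recovers_enthalpy(self, logK1, logK2, T1, dT):
        K1, K2, T2 = 10.0**logK1, 10.0**logK2, T1 + dT
        dH = enthalpy_from_two_points(K1, T1, K2, T2)
        assert vant_hoff_K(K1, dH, T1, T2) == pytest.approx(K2, rel=1e-9)
        # and the enthalpy itself round-trips through a re-inversion
        dH2 = enthalpy_from_two_points(K1, T1, vant_hoff_K(K1, dH, T1, T2), T2)
        assert dH2 == pytest.approx(dH, rel=1e-6, abs=1e-6)


class TestMassBalance:
    def test_empty_system(self):
        out = solve_mass_balance(0.0, 1e4, 1e6, 1.0)
        assert (out.n8, out.n4, out.n2, out.n, out.u) == (0, 0, 0, 0, 0)

    def test_melting_temperature_without_association(self):
        # K_U = 1, no dimers: C = [U](1 + 1/K_U) so [U] = [N] = C/2
        C = 1e-5
        out = solve_mass_balance(C, 0.0, 0.0, 1.0)
        assert out.u == pytest.approx(C / 2, rel=1e-12)
        assert out.n == pytest.approx(C / 2, rel=1e-12)

    def test_matches_bisection_oracle_at_spec_point(self):
        C, K_d, K_o, K_U = 1.5e-5, 2e6, 3.33e4, 1e-3
        u_oracle = brute_force_unfolded_root(C, K_o, K_d, K_U)
        out = solve_mass_balance(C, K_o, K_d, K_U)
        assert out.u == pytest.approx(u_oracle, rel=1e-12)

    def test_matches_bisection_oracle_on_random_draws(self, rng):
        for _ in range(100):
            C = 10.0 ** rng.uniform(-9, -2)
            K_o = 10.0 ** rng.uniform(2, 8)
            K_d = 10.0 ** rng.uniform(2, 8)
            K_U = 10.0 ** rng.uniform(-6, 3)
            out = solve_mass_balance(C, K_o, K_d, K_U)
            u_oracle = brute_force_unfolded_root(C, K_o, K_d, K_U)
            assert out.u == pytest.approx(u_oracle, rel=1e-12)
            assert abs(out.residual()) <= 1e-9 * C

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            solve_mass_balance(-1e-6, 1.0, 1.0, 1.0)
        with pytest.raises(InvalidParameterError):
            solve_mass_balance(1e-6, 1.0, 1.0, 0.0)


class TestPartitionTerms:
    def test_monomer_only_at_melting_temperature(self):
        concs = solve_mass_balance(1e-5, 0.0, 0.0, 1.0)
        terms = partition_terms(concs, 0.0, 0.0, 1.0)
        assert terms.Z == pytest.approx(2.0, rel=1e-12)
        assert terms.zN == 1.0

    def test_large_unfolding_limit(self):
        K_U = 1e8
        concs = solve_mass_balance(1e-5, 0.0, 0.0, K_U)
        terms = partition_terms(concs, 0.0, 0.0, K_U)
        assert terms.Z == pytest.approx(1.0 + K_U, rel=1e-9)
        assert terms.zU / terms.Z == pytest.approx(1.0, rel=1e-6)

    def test_two_partition_function_forms_agree(self, rng):
        # Z from equilibrium-constant powers vs Z = (total mass)/[N]
        for _ in range(50):
            C = 10.0 ** rng.uniform(-8, -3)
            K_o = 10.0 ** rng.uniform(2, 7)
            K_d = 10.0 ** rng.uniform(2, 8)
            K_U = 10.0 ** rng.uniform(-4, 2)
            concs = solve_mass_balance(C, K_o, K_d, K_U)
            terms = partition_terms(concs, K_o, K_d, K_U)
            Z_mass = (
                8 * concs.n8 + 4 * concs.n4 + 2 * concs.n2 + concs.n + concs.u
            ) / concs.n
            assert terms.Z == pytest.approx(Z_mass, rel=1e-9)

    def test_degenerate_state_raises(self):
        concs = solve_mass_balance(0.0, 1.0, 1.0, 1.0)
        with pytest.raises(DegenerateStateError):
            partition_terms(concs, 1.0, 1.0, 1.0)


class TestSpeciesFractions:
    def test_infinite_dilution_is_monomeric(self, wt150):
        sf = species_fractions(wt150, 1e-15, 300.15)
        assert sf.aN + sf.aU == pytest.approx(1.0, abs=1e-6)

    def test_fractions_sum_to_one_everywhere(self, wt150):
        for C in (1e-7, 1e-5, 2e-4):
            for T in (280.0, 298.15, 320.0, 355.0):
                sf = species_fractions(wt150, C, T)
                total = sf.a8 + sf.a4 + sf.a2 + sf.aN + sf.aU
                assert total == pytest.approx(1.0, abs=1e-9)
                for a in (sf.a8, sf.a4, sf.a2, sf.aN, sf.aU):
                    assert 0.0 <= a <= 1.0

    def test_octamer_fraction_grows_with_concentration(self, wt150):
        ladder = [1e-7, 1e-6, 1e-5, 5e-5, 2e-4]
        a8 = [species_fractions(wt150, C, 293.15).a8 for C in ladder]
        assert all(b >= a for a, b in zip(a8, a8[1:]))

    def test_native_ensemble_rank_order_at_15uM_37C(self, wt150):
        # dimers, then monomers, then tetramers dominate the native ensemble
        sf = species_fractions(wt150, 15e-6, 310.15)
        monomer = sf.aN + sf.aU
        assert sf.a2 > monomer > sf.a4


class TestHeatCapacity:
    def test_two_state_closed_form_in_monomer_only_limit(self):
        # without association, Cp(T_m) = dH_U^2 / (4 R T_m^2)
        dH_U, T_m = 3e5, 340.0
        params = ThermoParams(
            T_O=298.15, T_D=298.15, T_m=T_m, dH_O=0.0, dH_D=0.0, dH_U=dH_U,
            K_o_ref=1e-30, K_d_ref=1e-30,
        )
        grid = np.arange(300.0, 380.0, 0.5)
        curve = heat_capacity_curve(params, 1e-5, grid)
        K = vant_hoff_K(1.0, dH_U, T_m, grid)
        closed = K / (1 + K) ** 2 * dH_U**2 / (R * grid**2)
        np.testing.assert_allclose(curve.cp, closed, rtol=1e-3)
        at_tm = np.interp(T_m, grid, curve.cp)
        assert at_tm == pytest.approx(dH_U**2 / (4 * R * T_m**2), rel=1e-3)
        assert at_tm == pytest.approx(2.34e4, rel=5e-3)

    def test_zero_enthalpies_give_zero_excess_heat_capacity(self):
        params = ThermoParams(
            T_O=298.15, T_D=298.15, T_m=340.0, dH_O=0.0, dH_D=0.0, dH_U=0.0,
            K_o_ref=1e4, K_d_ref=1e6,
        )
        curve = heat_capacity_curve(params, 1e-5, np.arange(280.0, 360.0, 1.0))
        np.testing.assert_allclose(curve.cp, 0.0, atol=1e-6)

    def test_wt150_has_two_transitions_at_15uM(self, wt150):
        grid = np.arange(278.15, 368.15, 0.25)
        curve = heat_capacity_curve(wt150, 15e-6, grid)
        assert local_maxima(curve).size == 2

    def test_peak_temperature_non_decreasing_with_concentration(self, wt150):
        grid = np.arange(278.15, 368.15, 0.25)
        peaks = []
        for C in (15e-6, 50e-6, 100e-6, 141e-6):
            curve = heat_capacity_curve(wt150, C, grid)
            peaks.append(curve.T_grid[np.argmax(curve.cp)])
        assert all(b >= a for a, b in zip(peaks, peaks[1:]))

    def test_grid_validation(self, wt150):
        with pytest.raises(InvalidParameterError):
            heat_capacity_curve(wt150, 1e-5, np.array([240.0, 300.0]))
        with pytest.raises(InvalidParameterError):
            heat_capacity_curve(wt150, 1e-5, np.array([300.0, 299.0]))


def test_presets_are_anchored_to_printed_dissociation_constants():
    p = preset("wt_150mM")
    assert p.K_D_diss(298.15) == pytest.approx(0.5e-6, rel=1e-9)
    assert p.K_D_diss(310.15) == pytest.approx(8e-6, rel=1e-9)
    assert p.K_O_diss(298.15) == pytest.approx(30e-6, rel=1e-9)
    assert p.K_O_diss(310.15) == pytest.approx(45e-6, rel=1e-9)
    assert p.K_U(p.T_m) == pytest.approx(1.0, rel=1e-12)
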