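"""Closed-form transport equations against limits, algebra and the BVP oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ufsieve as uf
from ufsieve.transport import (
    DiffusionLimitWarning,
    UnphysicalValueWarning,
    solute_flux_membrane,
    solute_flux_polarization,
)

from conftest import random_microscopic


class TestPeclet:
    @pytest.mark.parametrize(
        "func,v,k,expected",
        [
            (uf.peclet_membrane, 7.34e-6, 7.34e-6, 1.0),
            (uf.peclet_membrane, 0.0, 1e-6, 0.0),
            (uf.peclet_membrane, 2e-5, 2e-6, 10.0),  # advection-dominated regime
            (uf.peclet_polarization, 7.34e-6, 7.34e-6, 1.0),
            (uf.peclet_polarization, 0.0, 7.34e-6, 0.0),
            (uf.peclet_polarization, 1.468e-5, 7.34e-6, 2.0),
        ],
    )
    def test_ratio(self, func, v, k, expected):
        assert func(v, k) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("func", [uf.peclet_membrane, uf.peclet_polarization])
    def test_nonpositive_coefficient_rejected(self, func):
        with pytest.raises(ValueError):
            func(1e-6, 0.0)
        with pytest.raises(ValueError):
            func(-1e-6, 1e-6)


class TestPartition:
    def test_ferry_bsa_example(self):
        # 3.48 nm protein in a 5.69 nm pore: ~15% can partition in
        phi = uf.ferry_partition(3.48e-9, 5.69e-9)
        assert phi == pytest.approx(0.1509, abs=5e-4)

    def test_ferry_point_solute_and_pore_filling(self):
        assert uf.ferry_partition(0.0, 1e-9) == 1.0
        assert uf.ferry_partition(1e-9, 1e-9) == 0.0
        # oversized solutes cannot re-enter via the squared form
        assert uf.ferry_partition(2.5e-9, 1e-9) == 0.0

    def test_ferry_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            uf.ferry_partition(-1e-9, 1e-9)
        with pytest.raises(ValueError):
            uf.ferry_partition(1e-9, 0.0)

    @given(st.floats(0.0, 1.0))
    def test_ferry_decreasing_in_solute_size(self, frac):
        r_p = 5e-9
        assert uf.ferry_partition(frac * r_p, r_p) <= uf.ferry_partition(
            0.99 * frac * r_p, r_p
        )

    def test_smith_deen_reduces_to_ferry_at_zero_energy(self):
        kT = 1.380649e-23 * 298.15
        p = uf.PartitionInputs(r_s=3.48e-9, r_p=5.69e-9, E_T=0.0, kT=kT)
        assert uf.smith_deen_partition(p) == uf.ferry_partition(3.48e-9, 5.69e-9)

    def test_smith_deen_boltzmann_factor(self):
        kT = 1.380649e-23 * 298.15
        p = uf.PartitionInputs(r_s=3.48e-9, r_p=5.69e-9, E_T=kT, kT=kT)
        expected = uf.ferry_partition(3.48e-9, 5.69e-9) * np.exp(-1.0)
        assert uf.smith_deen_partition(p) == pytest.approx(expected, rel=1e-12)
        assert uf.smith_deen_partition(p) == pytest.approx(0.0555, abs=2e-4)

    def test_smith_deen_infinite_repulsion(self):
        p = uf.PartitionInputs(r_s=1e-9, r_p=5e-9, E_T=np.inf, kT=4e-21)
        assert uf.smith_deen_partition(p) == 0.0


class TestSievingCoefficient:
    def test_total_exclusion_and_free_passage(self):
        assert uf.sieving_coefficient(1.0, 0.0) == 1.0
        assert uf.sieving_coefficient(1.0, 1.0) == 0.0

    def test_from_ferry_partition(self):
        phi = uf.ferry_partition(3.48e-9, 5.69e-9)
        assert uf.sieving_coefficient(1.0, phi) == pytest.approx(0.8491, abs=5e-4)

    def test_negative_sigma_warns_but_returns(self):
        with pytest.warns(UnphysicalValueWarning):
            assert uf.sieving_coefficient(1.5, 1.0) == pytest.approx(-0.5)


class TestRejectionEquations:
    def test_derived_point_values(self):
        # frozen from the numerical BVP oracle (and independent arithmetic)
        assert uf.rejection_general(0.9, 2.0, 1.0) == pytest.approx(0.4350, abs=5e-5)
        assert uf.rejection_advection(0.9, 2.0) == pytest.approx(0.5491, abs=5e-5)

    def test_purely_diffusive_membrane_passes_everything(self):
        for sigma in (0.2, 0.9, 1.0):
            assert uf.rejection_general(sigma, 1.0, 0.0) == 0.0

    def test_full_sieving(self):
        assert uf.rejection_general(1.0, 3.0, 2.0) == 1.0
        assert uf.rejection_advection(1.0, 3.0) == 1.0

    @given(st.floats(0.0, 1.0))
    def test_low_flux_limit_is_sigma(self, sigma):
        # R_obs at vanishing flux equals the sieving coefficient
        assert uf.rejection_advection(sigma, 0.0) == pytest.approx(sigma, abs=1e-12)
        assert uf.rejection_general(sigma, 0.0, np.inf) == pytest.approx(
            sigma, abs=1e-12
        )

    @given(st.floats(0.0, 0.999))
    def test_vanishing_rejection_at_high_polarization(self, sigma):
        assert uf.rejection_advection(sigma, 1e4) == pytest.approx(0.0, abs=1e-12)

    def test_numerical_stability_far_past_underflow(self):
        for pe in (700.0, 710.0, 1e6):
            r = uf.rejection_advection(0.5, pe)
            assert np.isfinite(r) and r == pytest.approx(0.0, abs=1e-300)
            assert np.isfinite(uf.rejection_general(0.5, pe, pe))

    def test_general_converges_to_advection_monotonically(self):
        sigmas = np.linspace(0.0, 1.0, 11)
        pe_ds = np.linspace(0.0, 10.0, 11)
        S, P = np.meshgrid(sigmas, pe_ds)
        prev = None
        for pe_m in (1.0, 2.0, 5.0, 10.0, 20.0):
            diff = np.abs(
                uf.rejection_general(S, P, pe_m) - uf.rejection_advection(S, P)
            )
            if prev is not None:
                assert np.all(diff <= prev + 1e-15)
            prev = diff
        assert np.max(prev) < 1e-8  # at Pe_m = 20

    def test_monotone_in_pe_d_and_sigma(self):
        pe = np.linspace(0.01, 10.0, 50)
        r = uf.rejection_advection(0.7, pe)
        assert np.all(np.diff(r) < 0)
        sig = np.linspace(0.01, 0.99, 50)
        r = uf.rejection_advection(sig, 2.0)
        assert np.all(np.diff(r) > 0)

    def test_strict_mode_rejects_unphysical_sigma(self):
        with pytest.raises(ValueError):
            uf.rejection_advection(1.2, 1.0, strict=True)
        with pytest.warns(UnphysicalValueWarning):
            uf.rejection_advection(1.2, 1.0)


class TestFluxExpressions:
    def test_no_solute_no_flux(self):
        assert solute_flux_membrane(0.0, 0.0, 1e-5, 1.0, 0.2, 2.0) == 0.0
        assert solute_flux_polarization(0.0, 0.0, 1e-5, 1.0) == 0.0

    def test_pure_advection_limits(self):
        # huge Pe: the layer simply advects its upstream concentration
        j = solute_flux_membrane(1.0, 1.0, 1e-5, 0.8, 0.2, 1e4)
        assert j == pytest.approx(0.8 * 0.2 * 1e-5 * 1.0, rel=1e-9)
        assert solute_flux_polarization(2.0, 2.0, 1e-5, 1.0) == pytest.approx(
            1e-5 * 2.0, rel=1e-12
        )

    def test_zero_peclet_is_flagged(self):
        with pytest.warns(DiffusionLimitWarning):
            assert solute_flux_polarization(1.0, 1.0, 0.0, 0.0) == 0.0
        with pytest.warns(DiffusionLimitWarning):
            assert np.isinf(solute_flux_polarization(1.0, 2.0, 0.0, 0.0))


class TestObservedRejection:
    @pytest.mark.parametrize(
        "c_ret,c_per,expected", [(1.0, 0.0, 1.0), (1.0, 1.0, 0.0), (5.0, 1.75, 0.65)]
    )
    def test_values(self, c_ret, c_per, expected):
        assert uf.observed_rejection(c_ret, c_per) == pytest.approx(expected)

    def test_errors_and_warnings(self):
        with pytest.raises(ValueError):
            uf.observed_rejection(0.0, 1.0)
        with pytest.warns(UnphysicalValueWarning):
            assert uf.observed_rejection(1.0, 2.0) == pytest.approx(-1.0)


class TestProfileOracle:
    def test_membrane_indistinguishable_from_solution(self):
        mp = uf.MicroscopicParameters(
            K_c=1.0, K_d=1.0, D_m=6e-11, D_i=6e-11,
            delta_mem=1e-6, delta_pol=1e-5, phi=1.0,
        )
        prof = uf.solve_profile_numeric(mp, 2e-6, 1.0)
        assert prof.c_p == pytest.approx(1.0, rel=1e-8)
        assert prof.rejection == pytest.approx(0.0, abs=1e-8)

    def test_total_exclusion(self):
        mp = uf.MicroscopicParameters(
            K_c=1.0, K_d=1.0, D_m=1e-11, D_i=6e-11,
            delta_mem=1e-6, delta_pol=1e-5, phi=0.0,
        )
        prof = uf.solve_profile_numeric(mp, 2e-6, 1.0)
        assert prof.c_p == 0.0 and prof.rejection == 1.0
        assert prof.c_m > 1.0  # polarization builds the wall concentration up

    def test_agrees_with_closed_form(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            mp, v_w, pe_d, pe_m = random_microscopic(rng)
            prof = uf.solve_profile_numeric(mp, v_w, 1.0)
            closed = uf.rejection_general(mp.sigma, pe_d, pe_m)
            assert prof.rejection == pytest.approx(closed, rel=1e-6)

    def test_flux_uniform_across_layers(self):
        rng = np.random.default_rng(3)
        mp, v_w, pe_d, pe_m = random_microscopic(rng)
        prof = uf.solve_profile_numeric(mp, v_w, 1.0)
        j_pol = solute_flux_polarization(prof.c_b, prof.c_m, v_w, pe_d)
        j_mem = solute_flux_membrane(prof.c_m, prof.c_p, v_w, mp.K_c, mp.phi, pe_m)
        scale = v_w * prof.c_b
        assert abs(j_pol - prof.J_i) / scale < 1e-8
        assert abs(j_mem - prof.J_i) / scale < 1e-8
        assert prof.J_i == pytest.approx(v_w * prof.c_p, rel=1e-12)

    def test_wall_concentration_exceeds_bulk_when_rejecting(self):
        rng = np.random.default_rng(9)
        mp, v_w, _, _ = random_microscopic(rng)
        prof = uf.solve_profile_numeric(mp, v_w, 1.0)
        if prof.rejection > 0:
            assert prof.c_m >= prof.c_b

    def test_invalid_inputs(self):
        mp = uf.MicroscopicParameters(
            K_c=1.0, K_d=1.0, D_m=1e-11, D_i=6e-11,
            delta_mem=1e-6, delta_pol=1e-5, phi=0.5,
        )
        with pytest.raises(ValueError):
            uf.solve_profile_numeric(mp, 0.0, 1.0)
        with pytest.raises(ValueError):
            uf.solve_profile_numeric(mp, 1e-6, -1.0)


class TestParameterTypes:
    def test_transport_parameter_invariants(self):
        with pytest.raises(ValueError):
            uf.TransportParameters(sigma=0.9, k_dbl=0.0)
        with pytest.raises(ValueError):
            uf.TransportParameters(sigma=0.9, k_dbl=1e-6, k_m=-1.0)
        uf.TransportParameters(sigma=1.0002, k_dbl=1e-6)  # permissive by default
        with pytest.raises(ValueError):
            uf.TransportParameters(sigma=1.0002, k_dbl=1e-6).validate_physical()

    def test_microscopic_parameter_invariants(self):
        with pytest.raises(ValueError):
            uf.MicroscopicParameters(
                K_c=1.0, K_d=1.0, D_m=0.0, D_i=1e-10,
                delta_mem=1e-6, delta_pol=1e-5, phi=0.5,
            )
        with pytest.raises(ValueError):
            uf.MicroscopicParameters(
                K_c=1.0, K_d=1.0, D_m=1e-11, D_i=1e-10,
                delta_mem=1e-6, delta_pol=1e-5, phi=0.5, K_f=1.5,
            )
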