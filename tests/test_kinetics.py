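"""Unit and property tests for the closed-form two-state model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import searchkin as sk
from searchkin.errors import InvalidParameterError, ParameterRangeError
from searchkin.kinetics import (
    LandscapeParameters,
    ModelParameters,
    base_timescale,
    chi_scan,
    d1d_to_si,
    diffusion_coefficient_1d,
    localization_probability,
    mean_scan_length,
    optimal_chi,
    recognition_probability,
    residence_rate,
    roughness_from_experimental_d1d,
    search_time,
    sliding_round_time,
    total_recognition_time,
    transition_rate,
)

KB = 1.380649e-23


class TestBaseTimescale:
    def test_default_parameters_hand_value(self, default_params):
        # hand evaluation of the rotation-coupled friction formula in SI:
        # eta=1e-3, R=R_OC=3 nm, BP=0.34 nm, T=298 K -> ~1.155e-7 s
        assert base_timescale(default_params) == pytest.approx(
            1.1554e-7, rel=1e-3)

    def test_rotation_suppressed_gives_stokes_time(self, default_params):
        expected = (6 * math.pi * 1e-3 * 3e-9 * (0.34e-9) ** 2
                    / (KB * 298.0))
        got = base_timescale(default_params, include_rotation=False)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_linear_in_viscosity(self, default_params):
        doubled = ModelParameters(viscosity=2e-3)
        assert base_timescale(doubled) == pytest.approx(
            2 * base_timescale(default_params), rel=1e-12)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(InvalidParameterError):
            ModelParameters(viscosity=0.0)
        with pytest.raises(InvalidParameterError):
            ModelParameters(protein_radius=-1e-9)
        with pytest.raises(InvalidParameterError):
            ModelParameters(genome_length=0.5)


class TestDiffusionAndResidence:
    def test_zero_roughness_limit(self):
        tau0 = 2e-7
        assert diffusion_coefficient_1d(0.0, tau0) == pytest.approx(1 / tau0)

    def test_sigma_two(self):
        tau0 = 2e-7
        assert diffusion_coefficient_1d(2.0, tau0) == pytest.approx(
            math.exp(-4.0) / tau0, rel=1e-12)

    def test_immobile_at_target_roughness(self):
        tau0 = 1e-7
        ratio = (diffusion_coefficient_1d(5.0, tau0)
                 / diffusion_coefficient_1d(0.0, tau0))
        assert ratio == pytest.approx(math.exp(-25.0), rel=1e-12)

    def test_negative_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            diffusion_coefficient_1d(-0.1, 1e-7)

    def test_residence_rate_substitution(self):
        tau0 = 1e-7
        assert residence_rate(1 / tau0) == pytest.approx(4 / tau0)

    def test_residence_rate_chain_sigma2(self):
        # Eq chain with the printed rounded tau0 = 1.2e-7 s
        tau0 = 1.2e-7
        k = residence_rate(diffusion_coefficient_1d(2.0, tau0))
        assert k == pytest.approx(6.1e5, rel=0.01)

    def test_residence_rate_linear(self):
        assert residence_rate(500.0) == pytest.approx(
            residence_rate(1000.0) / 2)


class TestSlidingRound:
    def test_zero_energy_limit(self):
        assert sliding_round_time(0.0, 0.0, 3e-7) == pytest.approx(3e-7)

    def test_ens5_sigma2(self):
        tau0 = 1e-7
        assert sliding_round_time(5.0, 2.0, tau0) == pytest.approx(
            tau0 * math.exp(7.0), rel=1e-12)

    def test_four_orders_of_magnitude_in_ens(self):
        # dwell grows by e^10 (~4.3 orders of magnitude) from E_ns=5 to 15
        tau0 = 1e-7
        ratio = (sliding_round_time(15.0, 1.0, tau0)
                 / sliding_round_time(5.0, 1.0, tau0))
        assert ratio == pytest.approx(math.exp(10.0), rel=1e-12)
        assert math.log10(ratio) > 4.0

    def test_overflow_guarded(self):
        with pytest.raises(ParameterRangeError):
            sliding_round_time(800.0, 0.0, 1e-7)


class TestScanLengthAndRates:
    def test_unit_case(self):
        tau0 = 1e-7
        assert mean_scan_length(1 / tau0, tau0) == pytest.approx(2.0)

    def test_closed_form_ens5(self):
        # <n> = 2 exp(E_ns/2 - sigma^2/4)
        tau0 = 1e-7
        d = diffusion_coefficient_1d(0.0, tau0)
        t1 = sliding_round_time(5.0, 0.0, tau0)
        assert mean_scan_length(d, t1) == pytest.approx(
            2 * math.exp(2.5), rel=1e-12)

    def test_monotone_decreasing_in_sigma(self):
        tau0 = 1e-7
        lengths = [
            mean_scan_length(diffusion_coefficient_1d(s, tau0),
                             sliding_round_time(5.0, s, tau0))
            for s in (0.0, 1.0, 2.0, 3.0)]
        assert all(a > b for a, b in zip(lengths, lengths[1:]))

    def test_transition_rate_limits(self):
        tau0 = 1e-7
        assert transition_rate(0.0, tau0) == pytest.approx(1 / tau0)
        assert transition_rate(3.5, tau0) == pytest.approx(
            math.exp(-3.5) / tau0, rel=1e-12)
        ratio = transition_rate(7.0, tau0) / transition_rate(3.5, tau0)
        assert ratio == pytest.approx(math.exp(-3.5), rel=1e-12)


class TestProbabilities:
    def test_symmetric_race(self):
        assert recognition_probability(10.0, 10.0) == pytest.approx(0.5)

    def test_no_escape(self):
        assert recognition_probability(5.0, 0.0) == pytest.approx(1.0)

    def test_hand_value(self):
        tau0 = 1e-7
        p = recognition_probability(math.exp(-3.5) / tau0, 4 / tau0)
        assert p == pytest.approx(7.49e-3, rel=1e-3)

    def test_both_zero_undefined(self):
        with pytest.raises(InvalidParameterError):
            recognition_probability(0.0, 0.0)

    def test_localization_clamp_and_product(self):
        assert localization_probability(100.0, 0.5) == 1.0
        assert localization_probability(24.4, 7.49e-3) == pytest.approx(
            0.1828, rel=1e-3)
        assert localization_probability(1.5, 1.0) == 1.0


class TestSearchAndTotalTime:
    def test_single_round_genome(self):
        p = ModelParameters(genome_length=24.0, tau_3d=1e-4)
        assert search_time(p, 2e-4, 24.0) == pytest.approx(3e-4)

    def test_fig_scale_substitution(self):
        tau0 = base_timescale(ModelParameters())
        p = ModelParameters(genome_length=5e6, tau_3d=0.0)
        tau1d = tau0 * math.exp(5.0)
        n = 2 * math.exp(2.5)
        assert search_time(p, tau1d, n) == pytest.approx(
            5e6 / n * tau1d, rel=1e-12)

    def test_linear_in_genome_length(self):
        p1 = ModelParameters(genome_length=1e6)
        p2 = ModelParameters(genome_length=3e6)
        assert search_time(p2, 1e-4, 20.0) == pytest.approx(
            3 * search_time(p1, 1e-4, 20.0), rel=1e-12)

    def test_frictionless_barrierless_limit(self, default_params):
        b = total_recognition_time(
            LandscapeParameters(chi=0.5, dg_max=0.0, e_ns=5.0, sigma_max=0.0),
            default_params)
        assert b.p_loc == 1.0
        assert b.tau_r == b.tau_s

    def test_chained_formula_against_independent_expression(self):
        # single-expression derivation of the whole chain at chi=0:
        # sigma=0, dG=dg_max, so
        # tau_R = (M exp(E)/(2 exp(E/2))) * tau0
        #         / min(1, 2 exp(E/2) * e^-dG/(e^-dG + 4))
        p = ModelParameters(genome_length=5e6)
        tau0 = base_timescale(p)
        e, dg = 5.0, 5.0
        expected = (5e6 * math.exp(e) / (2 * math.exp(e / 2)) * tau0
                    / min(1.0, 2 * math.exp(e / 2) * math.exp(-dg)
                          / (math.exp(-dg) + 4.0)))
        b = total_recognition_time(
            LandscapeParameters(chi=0.0, dg_max=dg, e_ns=e, sigma_max=5.0), p)
        assert b.tau_r == pytest.approx(expected, rel=1e-12)

    def test_full_similarity_no_barrier_limit(self, default_params):
        # chi=1, dG_max=0: P_f -> 1, so tau_R -> tau_S(sigma_max)/min(1,<n>)
        b = total_recognition_time(
            LandscapeParameters(chi=1.0, dg_max=0.0, e_ns=5.0, sigma_max=5.0),
            default_params)
        assert b.tau_r == pytest.approx(
            b.tau_s / min(1.0, b.n_mean), rel=1e-9)


class TestLandscapeParameters:
    def test_derived_quantities_exact(self):
        lp = LandscapeParameters(chi=0.3, dg_max=5.0, e_ns=5.0, sigma_max=5.0)
        assert lp.sigma == 0.3 * 5.0
        assert lp.dg_barrier == 5.0 * 0.7

    def test_negative_chi_rejected(self):
        with pytest.raises(InvalidParameterError):
            LandscapeParameters(chi=-0.1, dg_max=5.0, e_ns=5.0)

    def test_chi_above_one_clamped(self):
        lp = LandscapeParameters(chi=1.2, dg_max=5.0, e_ns=5.0)
        assert lp.chi == 1.0

    def test_anticorrelation_of_sigma_and_barrier(self):
        chis = np.linspace(0, 1, 11)
        lps = [LandscapeParameters(chi=c, dg_max=7.0, e_ns=5.0) for c in chis]
        sigmas = [lp.sigma for lp in lps]
        barriers = [lp.dg_barrier for lp in lps]
        assert all(a <= b for a, b in zip(sigmas, sigmas[1:]))
        assert all(a >= b for a, b in zip(barriers, barriers[1:]))


class TestChiScan:
    def test_low_barrier_regime_prefers_frustration(self, default_params):
        t = chi_scan([0.0, 0.5, 1.0],
                     LandscapeParameters(chi=0, dg_max=0.0, e_ns=5.0,
                                         sigma_max=5.0), default_params)
        assert t.tau_r_s.is_monotonic_increasing
        assert t.tau_r_s.is_unique

    def test_smooth_sliding_regime_prefers_similarity(self, default_params):
        t = chi_scan([0.0, 0.5, 1.0],
                     LandscapeParameters(chi=0, dg_max=10.0, e_ns=5.0,
                                         sigma_max=0.0), default_params)
        assert t.tau_r_s.is_monotonic_decreasing
        assert t.tau_r_s.is_unique

    def test_single_point_matches_total(self, default_params):
        lp = LandscapeParameters(chi=0, dg_max=5.0, e_ns=5.0)
        t = chi_scan([0.3], lp, default_params)
        b = total_recognition_time(lp.with_chi(0.3), default_params)
        assert t.tau_r_s.iloc[0] == b.tau_r
        assert t.tau1d_s.iloc[0] == b.tau_1d

    def test_bad_grids_rejected(self, default_params):
        lp = LandscapeParameters(chi=0, dg_max=5.0, e_ns=5.0)
        for bad in ([], [0.5, 0.2], [-0.1, 0.5], [0.5, 1.5]):
            with pytest.raises(InvalidParameterError):
                chi_scan(bad, lp, default_params)


class TestOptimalChi:
    def test_barrierless_boundary(self, default_params):
        chi, _ = optimal_chi(
            LandscapeParameters(chi=0, dg_max=0.0, e_ns=5.0, sigma_max=5.0),
            default_params, 0.01)
        assert chi == 0.0

    def test_smooth_sliding_boundary(self, default_params):
        chi, _ = optimal_chi(
            LandscapeParameters(chi=0, dg_max=10.0, e_ns=5.0, sigma_max=0.0),
            default_params, 0.01)
        assert chi == 1.0

    def test_interior_optimum_matches_dense_grid(self, default_params):
        lp = LandscapeParameters(chi=0, dg_max=5.0, e_ns=5.0, sigma_max=5.0)
        chi, tau = optimal_chi(lp, default_params, 1e-2)
        assert 0.0 < chi < 1.0
        dense = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        vals = [total_recognition_time(lp.with_chi(c), default_params).tau_r
                for c in dense]
        brute = dense[int(np.argmin(vals))]
        assert chi == pytest.approx(brute, abs=1e-4)
        assert tau <= min(vals)

    def test_u_shape_single_interior_minimum(self, default_params):
        lp = LandscapeParameters(chi=0, dg_max=5.0, e_ns=5.0, sigma_max=5.0)
        t = chi_scan(np.round(np.arange(0, 1.0 + 1e-9, 0.01), 10), lp,
                     default_params)
        v = t.tau_r_s.to_numpy()
        interior_minima = [
            i for i in range(1, len(v) - 1)
            if v[i] < v[i - 1] and v[i] < v[i + 1]]
        assert len(interior_minima) == 1
        # and the boundaries are not minima
        assert v[0] > v[1] or v[0] > v[interior_minima[0]]
        assert v[-1] > v[-2] or v[-1] > v[interior_minima[0]]

    def test_bad_resolution(self, default_params):
        lp = LandscapeParameters(chi=0, dg_max=5.0, e_ns=5.0)
        with pytest.raises(InvalidParameterError):
            optimal_chi(lp, default_params, 0.0)


class TestRoughnessInversion:
    def test_ceiling_gives_zero(self, default_params):
        tau0 = base_timescale(default_params)
        ceiling = default_params.bp_rise ** 2 / tau0
        assert roughness_from_experimental_d1d(
            ceiling, default_params) == 0.0

    def test_exact_roundtrip_sigma2(self, default_params):
        tau0 = base_timescale(default_params)
        d = d1d_to_si(diffusion_coefficient_1d(2.0, tau0),
                      default_params.bp_rise)
        assert roughness_from_experimental_d1d(
            d, default_params) == pytest.approx(2.0, rel=1e-12)

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5,
                                       4.0, 4.5, 5.0])
    def test_roundtrip_property(self, sigma, default_params):
        tau0 = base_timescale(default_params)
        d = d1d_to_si(diffusion_coefficient_1d(sigma, tau0),
                      default_params.bp_rise)
        back = roughness_from_experimental_d1d(d, default_params)
        assert back == pytest.approx(sigma, rel=1e-10)

    def test_above_ceiling_rejected(self, default_params):
        tau0 = base_timescale(default_params)
        ceiling = default_params.bp_rise ** 2 / tau0
        with pytest.raises(InvalidParameterError, match="ceiling"):
            roughness_from_experimental_d1d(2 * ceiling, default_params)


@st.composite
def valid_landscapes(draw):
    chi = draw(st.floats(0.0, 1.0))
    sigma_max = draw(st.floats(0.0, 6.0))
    dg_max = draw(st.floats(0.0, 15.0))
    e_ns = draw(st.floats(0.0, 15.0))
    return LandscapeParameters(chi=chi, dg_max=dg_max, e_ns=e_ns,
                               sigma_max=sigma_max)


class TestAlgebraicIdentities:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(lp=valid_landscapes(),
           m=st.floats(10.0, 1e7))
    def test_exact_identities(self, lp, m):
        p = ModelParameters(genome_length=m)
        b = total_recognition_time(lp, p)
        assert b.tau_1d * b.k_off == pytest.approx(1.0, rel=1e-12)
        assert b.n_mean ** 2 == pytest.approx(4 * b.d1d * b.tau_1d,
                                              rel=1e-12)
        assert b.tau_r * b.p_loc == pytest.approx(b.tau_s, rel=1e-12)
        assert 0.0 < b.p_f <= 1.0
        assert 0.0 < b.p_loc <= 1.0
        assert b.tau_r >= b.tau_s

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(e=st.floats(0.0, 14.0), s=st.floats(0.0, 5.5),
           step=st.floats(0.1, 1.0))
    def test_monotonicity(self, e, s, step):
        tau0 = 1e-7
        assert (sliding_round_time(e + step, s, tau0)
                > sliding_round_time(e, s, tau0))
        assert (sliding_round_time(e, s + step, tau0)
                > sliding_round_time(e, s, tau0))
        assert (diffusion_coefficient_1d(s + step, tau0)
                < diffusion_coefficient_1d(s, tau0))
        assert transition_rate(e + step, tau0) < transition_rate(e, tau0)
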