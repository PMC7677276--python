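"""Dosage-form kinetics: Higuchi release, base removal, dose splitting,
particle dissolution and pre-corneal overflow."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from ocupbpk import formulation as fk


class TestKOintment:
    @pytest.mark.parametrize(
        "dose_mg, at_h, expected_mg_per_h",
        [(0.050, 5.0, 0.010), (0.025, 3.5, 7.143e-3)],
    )
    def test_zero_order_rate_from_dose_and_application_time(self, dose_mg, at_h, expected_mg_per_h):
        rate_mg_s = fk.k_ointment(dose_mg, at_h * 3600.0)
        assert rate_mg_s * 3600.0 == pytest.approx(expected_mg_per_h, rel=1e-3)

    def test_rate_vanishes_for_long_application_time(self):
        assert fk.k_ointment(0.050, 1e12) == pytest.approx(0.0, abs=1e-12)

    def test_rate_times_application_time_recovers_dose(self):
        for dose, at in [(0.05, 18000.0), (0.025, 12600.0), (1.3, 7.0)]:
            assert fk.k_ointment(dose, at) * at == pytest.approx(dose, rel=1e-14)

    @pytest.mark.parametrize("dose, at", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_non_positive_inputs_rejected(self, dose, at):
        with pytest.raises(ValueError):
            fk.k_ointment(dose, at)


class TestHiguchiRelease:
    def test_rate_at_one_second_with_reference_parameters(self):
        # SA * kH * t^(-1/2) at t=1 s, SA=1.763 cm2, kH=2.7e-6
        rate = fk.higuchi_release_rate(1.0, 1.763, 2.7e-6, unreleased_mass=1.0)
        assert rate == pytest.approx(4.760e-6, rel=1e-3)

    def test_zero_constant_and_exhausted_reservoir_give_zero(self):
        assert fk.higuchi_release_rate(10.0, 1.763, 0.0, unreleased_mass=1.0) == 0.0
        assert fk.higuchi_release_rate(10.0, 1.763, 2.7e-6, unreleased_mass=0.0) == 0.0

    def test_time_floor_bounds_the_singularity(self):
        r0 = fk.higuchi_release_rate(0.0, 1.0, 1.0, 1.0, time_floor=0.1)
        assert r0 == pytest.approx(1.0 / math.sqrt(0.1))

    def test_cumulative_reference_value_five_hours(self):
        # 2 * SA * kH * sqrt(t) for the 50 ug ointment over its 5 h application
        assert fk.higuchi_cumulative(18000.0, 1.763, 2.7e-6) == pytest.approx(1.2775e-3, rel=1e-3)

    def test_cumulative_empty_interval_is_zero(self):
        assert fk.higuchi_cumulative(0.0, 1.763, 2.7e-6) == 0.0

    def test_quadrupling_time_doubles_cumulative_release(self):
        c1 = fk.higuchi_cumulative(500.0, 1.2, 3e-6)
        c4 = fk.higuchi_cumulative(2000.0, 1.2, 3e-6)
        assert c4 == pytest.approx(2 * c1, rel=1e-12)

    def test_cumulative_matches_adaptive_quadrature_of_rate(self):
        # closed form vs quadrature of SA*kH*t^(-1/2) on random parameter triples
        rng = np.random.default_rng(42)
        for _ in range(100):
            sa = rng.uniform(0.1, 5.0)
            kh = 10.0 ** rng.uniform(-7, -4)
            t = 10.0 ** rng.uniform(0, 5)
            # algebraic-singularity weighting integrates u^(-1/2) exactly
            oracle, _ = quad(lambda u: sa * kh, 0.0, t, weight="alg", wvar=(-0.5, 0))
            assert fk.higuchi_cumulative(t, sa, kh) == pytest.approx(oracle, rel=1e-6)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fk.higuchi_release_rate(1.0, -1.0, 1e-6, 1.0)
        with pytest.raises(ValueError):
            fk.higuchi_cumulative(-1.0, 1.0, 1e-6)


class TestSiepmannEstimate:
    @pytest.mark.parametrize(
        "cini, d, cs, expected",
        [
            (1.0, 9.6e-9, 0.0155, 1.73e-5),    # fluorometholone in ointment base
            (60.0, 5.6e-8, 1.4, 3.067e-3),     # 6% acyclovir
            (0.0, 9.6e-9, 0.0155, 0.0),
        ],
    )
    def test_closed_form_sqrt_2_cini_d_cs(self, cini, d, cs, expected):
        assert fk.siepmann_khiguchi(cini, d, cs) == pytest.approx(expected, rel=5e-3, abs=1e-15)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            fk.siepmann_khiguchi(-1.0, 1e-9, 0.01)


class TestSuspensionSplit:
    @pytest.mark.parametrize(
        "conc, vol, sol, dissolved, suspended",
        [
            (1.0, 0.050, 0.0155, 0.000775, 0.049225),   # 0.1% x 50 uL
            (0.1, 0.050, 0.0155, 0.000775, 0.004225),   # 0.01% x 50 uL
            (0.01, 0.050, 0.0155, 0.0005, 0.0),         # below solubility: all dissolved
        ],
    )
    def test_solubility_capped_split(self, conc, vol, sol, dissolved, suspended):
        d, s = fk.split_suspension_dose(conc, vol, sol)
        assert d == pytest.approx(dissolved, rel=1e-9)
        assert s == pytest.approx(suspended, rel=1e-9, abs=1e-15)

    def test_split_conserves_total_dose_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            conc, vol, sol = rng.uniform(0.01, 10), rng.uniform(0.01, 0.1), rng.uniform(1e-3, 1.0)
            d, s = fk.split_suspension_dose(conc, vol, sol)
            assert d + s == conc * vol
            assert d >= 0 and s >= 0


class TestLFJDissolution:
    ARGS = dict(d_aq=5e-6, density_g_ml=1.2, c_s=0.0155, c_bulk=0.0)

    def test_nothing_suspended_gives_zero(self):
        assert fk.lfj_dissolution_rate(0.0, 0.05, 2.0, **self.ARGS) == 0.0

    def test_saturation_halts_dissolution(self):
        args = dict(self.ARGS, c_bulk=0.0155)
        assert fk.lfj_dissolution_rate(0.05, 0.05, 2.0, **args) == 0.0

    def test_rate_decreases_with_initial_radius(self):
        r_small = fk.lfj_dissolution_rate(0.04, 0.05, 2.0, **self.ARGS)
        r_large = fk.lfj_dissolution_rate(0.04, 0.05, 10.4, **self.ARGS)
        assert r_small > r_large > 0

    def test_rate_decreases_with_bulk_concentration(self):
        rates = [
            fk.lfj_dissolution_rate(0.04, 0.05, 2.0, 5e-6, 1.2, 0.0155, cb)
            for cb in (0.0, 0.005, 0.010, 0.0154)
        ]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_boundary_layer_capped_at_30_um(self):
        # above 30 um the diffusion layer stops growing with radius, so the
        # rate scales as 1/r0 instead of 1/r0^2
        r40 = fk.lfj_dissolution_rate(0.05, 0.05, 40.0, **self.ARGS)
        r80 = fk.lfj_dissolution_rate(0.05, 0.05, 80.0, **self.ARGS)
        assert r40 / r80 == pytest.approx(2.0, rel=1e-9)

    def test_invalid_radius_or_density_rejected(self):
        with pytest.raises(ValueError):
            fk.lfj_dissolution_rate(0.05, 0.05, 0.0, **self.ARGS)
        with pytest.raises(ValueError):
            fk.lfj_dissolution_rate(0.05, 0.05, 2.0, 5e-6, 0.0, 0.0155, 0.0)


class TestOverflow:
    def test_reference_overflow_50ul_into_35ul_sac(self):
        frac = fk.overflow_retained_fraction(50.0, 7.5, 35.0)
        assert frac == pytest.approx(0.55, rel=1e-12)

    def test_no_overflow_when_dose_fits(self):
        assert fk.overflow_retained_fraction(20.0, 7.5, 35.0) == 1.0

    def test_ointment_exempt_from_overflow(self):
        assert fk.overflow_retained_fraction(50.0, 7.5, 35.0, variant="ointment") == 1.0

    def test_baseline_at_capacity_rejected(self):
        with pytest.raises(ValueError):
            fk.overflow_retained_fraction(50.0, 35.0, 35.0)
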