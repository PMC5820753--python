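"""Kinetic conversions: traces -> k_obs -> k_gb -> physiological predictions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from racemkit import (
    BLOOD_EQUIVALENT_BUFFER,
    BufferSpec,
    ExposureScenario,
    FixtureSpec,
    KineticTrace,
    RateMeasurement,
    base_concentration,
    classify_risk,
    correct_hydrolysis,
    extract_kgb,
    fit_first_order,
    gen_buffer_series,
    gen_trace,
    half_life,
    predict,
    protonation_correction,
    racemized_fraction,
    temperature_correction,
)


class TestBaseConcentration:
    def test_half_dissociated_at_pka(self):
        b = BufferSpec(total_concentration=0.15, ph=6.80, pka=6.80)
        assert base_concentration(b) == pytest.approx(0.075)

    def test_blood_equivalent_buffer(self):
        assert base_concentration(BLOOD_EQUIVALENT_BUFFER) == pytest.approx(
            0.15 / (1 + 10 ** (6.80 - 7.2))
        )
        assert base_concentration(BLOOD_EQUIVALENT_BUFFER) == pytest.approx(0.1073, abs=1e-4)

    def test_fully_deprotonated_limit(self):
        b = BufferSpec(total_concentration=0.15, ph=12.8, pka=6.8)
        assert base_concentration(b) == pytest.approx(0.15, rel=1e-4)

    def test_speciation_conserves_total(self):
        for ph in (3.0, 6.8, 7.2, 10.0):
            b = BufferSpec(total_concentration=0.15, ph=ph, pka=6.8)
            base = base_concentration(b)
            acid = b.total_concentration - base
            assert base + acid == pytest.approx(0.15, abs=1e-12)

    def test_invalid_buffer_rejected(self):
        with pytest.raises(ValueError):
            BufferSpec(total_concentration=0.0, ph=7.0, pka=7.0)
        with pytest.raises(ValueError):
            BufferSpec(total_concentration=0.1, ph=15.0, pka=7.0)


class TestFitFirstOrder:
    def test_noiseless_exact_recovery(self):
        trace, truth = gen_trace(1e-4, amplitude=100.0, baseline=0.0,
                                 spec=FixtureSpec(seed=0, noise_sigma=0.0, n_points=50))
        fit = fit_first_order(trace)
        assert fit["k_obs"] == pytest.approx(truth["k_obs"], rel=1e-9)
        assert fit["amplitude"] == pytest.approx(100.0, rel=1e-6)
        assert fit["baseline"] == pytest.approx(0.0, abs=1e-6)

    def test_noisy_recovery_within_three_se(self):
        trace, truth = gen_trace(5e-5, amplitude=100.0, baseline=0.0,
                                 spec=FixtureSpec(seed=7, noise_sigma=1.0, n_points=50))
        fit = fit_first_order(trace)
        assert abs(fit["k_obs"] - truth["k_obs"]) < 3 * fit["k_obs_se"]

    def test_hd_exchange_round_trip(self):
        trace, truth = gen_trace(2e-4, amplitude=0.95, baseline=0.0,
                                 spec=FixtureSpec(seed=1, noise_sigma=0.0, n_points=30),
                                 kind="hd_exchange")
        fit = fit_first_order(trace)
        assert fit["k_obs"] == pytest.approx(2e-4, rel=1e-9)
        assert fit["amplitude"] == pytest.approx(0.95, rel=1e-6)  # the plateau

    def test_four_points_rejected(self):
        with pytest.raises(ValueError):
            KineticTrace(times_s=[0, 1, 2, 3], signal=[3, 2, 1, 0.5])

    def test_constant_signal_rejected(self):
        trace = KineticTrace(times_s=[0, 1, 2, 3, 4], signal=[5.0] * 5)
        with pytest.raises(ValueError, match="constant"):
            fit_first_order(trace)

    def test_unbiased_over_replicates(self):
        """|mean bias| stays below the typical per-fit standard error."""
        k_true = 5e-5
        estimates, ses = [], []
        for rep in range(200):
            trace, _ = gen_trace(k_true, amplitude=100.0, baseline=0.0,
                                 spec=FixtureSpec(seed=10_000 + rep, noise_sigma=1.0,
                                                  n_points=40))
            fit = fit_first_order(trace)
            estimates.append(fit["k_obs"])
            ses.append(fit["k_obs_se"])
        bias = float(np.mean(estimates)) - k_true
        assert abs(bias) < float(np.mean(ses))


class TestCorrectHydrolysis:
    def test_identity_without_hydrolysis(self):
        assert correct_hydrolysis(1.2e-5, 0.0) == pytest.approx(1.2e-5)

    def test_subtraction(self):
        assert correct_hydrolysis(1.2e-5, 0.2e-5) == pytest.approx(1.0e-5)

    def test_small_negative_floors_at_zero(self):
        with pytest.warns(UserWarning):
            assert correct_hydrolysis(1.0e-5, 1.1e-5, k_obs_se=1e-6, k_hydrolysis_se=1e-6) == 0.0

    def test_unphysical_excess_rejected(self):
        with pytest.raises(ValueError):
            correct_hydrolysis(1.0e-5, 2.0e-5, k_obs_se=1e-7, k_hydrolysis_se=1e-7)


class TestExtractKgb:
    def test_exact_line(self):
        meas = [
            RateMeasurement(c, 1e-6 + 2e-4 * c)
            for c in (0.02, 0.05, 0.1, 0.2, 0.4)
        ]
        res = extract_kgb(meas)
        assert res["kgb"] == pytest.approx(2e-4, rel=1e-9)
        assert res["intercept"] == pytest.approx(1e-6, rel=1e-9)
        assert not res["negative_slope"]

    def test_noisy_recovery_within_three_se(self):
        meas, truth = gen_buffer_series(
            5e-5, 0.0, [0.02, 0.05, 0.1, 0.2, 0.35, 0.5],
            spec=FixtureSpec(seed=11, noise_sigma=0.05),
        )
        res = extract_kgb(meas)
        assert abs(res["kgb"] - truth["kgb"]) < 3 * res["kgb_se"]

    def test_unbiased_over_replicates(self):
        kgb_true = 5e-5
        estimates, ses = [], []
        for rep in range(200):
            meas, _ = gen_buffer_series(
                kgb_true, 1e-7, [0.02, 0.05, 0.1, 0.2, 0.35, 0.5],
                spec=FixtureSpec(seed=20_000 + rep, noise_sigma=0.05),
            )
            res = extract_kgb(meas)
            estimates.append(res["kgb"])
            ses.append(res["kgb_se"])
        bias = float(np.mean(estimates)) - kgb_true
        assert abs(bias) < float(np.mean(ses))

    def test_single_concentration_rejected(self):
        meas = [RateMeasurement(0.1, 1e-5)] * 3
        with pytest.raises(ValueError):
            extract_kgb(meas)

    def test_negative_slope_flagged_not_clipped(self):
        meas = [RateMeasurement(c, 1e-5 - 1e-5 * c) for c in (0.1, 0.3, 0.5)]
        with pytest.warns(UserWarning):
            res = extract_kgb(meas)
        assert res["kgb"] < 0 and res["negative_slope"]


class TestScalarCorrections:
    def test_protonation_identity_and_scaling(self):
        assert protonation_correction(2e-4, 1.0) == pytest.approx(2e-4)
        assert protonation_correction(2e-4, 0.5) == pytest.approx(4e-4)
        with pytest.raises(ValueError):
            protonation_correction(2e-4, 0.0)

    def test_temperature_identity(self):
        assert temperature_correction(1e-4, 298.15, 298.15, 20.0) == pytest.approx(1e-4)
        assert temperature_correction(1e-4, 298.15, 310.15, 0.0) == pytest.approx(1e-4)

    def test_arrhenius_factor(self):
        # 20 kcal/mol barrier, 25 C -> 37 C is about a 3.7-fold acceleration
        factor = temperature_correction(1.0, 298.15, 310.15, 20.0)
        expected = math.exp((20.0 / 1.987204258640832e-3) * (1 / 298.15 - 1 / 310.15))
        assert factor == pytest.approx(expected, rel=1e-12)
        assert factor == pytest.approx(3.69, abs=0.01)


class TestRacemizedFraction:
    def test_zero_duration(self):
        sc = ExposureScenario(duration_s=0.0)
        assert racemized_fraction(1e-4, sc) == 0.0

    def test_table_row_with_sigma_ddg_minus_48_8(self):
        # the non-aromatic line at -48.8 kcal/mol under blood-equivalent
        # conditions racemizes ~28% in 24 h
        kgb = 10 ** (-0.11 * -48.8 - 9.81)
        frac = racemized_fraction(kgb)
        assert frac == pytest.approx(0.285, abs=0.005)

    def test_long_duration_saturates_at_one(self):
        sc = ExposureScenario(duration_s=1e12)
        assert racemized_fraction(1e-4, sc) == pytest.approx(1.0, abs=1e-12)

    def test_negative_kgb_rejected(self):
        with pytest.raises(ValueError):
            racemized_fraction(-1e-5)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(1e-8, 1e-2), st.floats(1e-8, 1e-2),
        st.floats(1e2, 1e6), st.floats(1e2, 1e6),
    )
    def test_monotone_in_rate_and_duration(self, k1, k2, t1, t2):
        klo, khi = sorted((k1, k2))
        tlo, thi = sorted((t1, t2))
        assert racemized_fraction(klo, ExposureScenario(duration_s=tlo)) <= racemized_fraction(
            khi, ExposureScenario(duration_s=tlo)
        )
        assert racemized_fraction(khi, ExposureScenario(duration_s=tlo)) <= racemized_fraction(
            khi, ExposureScenario(duration_s=thi)
        )

    def test_monotone_in_base_concentration(self):
        fr = [
            racemized_fraction(1e-4, ExposureScenario(
                buffer=BufferSpec(total_concentration=c, ph=7.2, pka=6.8)))
            for c in (0.05, 0.1, 0.2, 0.4)
        ]
        assert fr == sorted(fr)

    def test_closed_form_matches_ode_integration(self):
        """ee decay d(ee)/dt = -k ee integrated numerically matches exp(-kt)."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = 10 ** rng.uniform(-7, -3)
            t = 10 ** rng.uniform(2, 6)
            sol = solve_ivp(
                lambda _t, ee: -k * ee, (0.0, t), [1.0],
                rtol=1e-11, atol=1e-14, method="RK45", dense_output=False,
            )
            ee_num = sol.y[0, -1]
            assert ee_num == pytest.approx(math.exp(-k * t), rel=1e-8)


class TestHalfLifeAndRisk:
    @settings(max_examples=100, derandomize=True)
    @given(st.floats(1e-10, 1e-1))
    def test_half_life_times_k_is_ln2(self, k):
        assert half_life(k) * k == pytest.approx(math.log(2), rel=1e-12)

    def test_zero_rate_half_life_is_infinite(self):
        assert half_life(0.0) == math.inf

    @pytest.mark.parametrize(
        "frac,expected",
        [
            (0.0, "low"),
            (0.005, "low"),
            (0.01, "medium"),
            (0.10, "medium"),  # closed upper bound
            (0.101, "high"),
            (0.285, "high"),
        ],
    )
    def test_default_thresholds(self, frac, expected):
        assert classify_risk(frac) == expected

    def test_malformed_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_risk(0.5, {"low": 0.5, "medium": 0.1})

    def test_predict_assembles_consistent_report(self):
        p = predict(-4.442, rmse=0.40)
        assert p.half_life_s * p.k_obs == pytest.approx(math.log(2), rel=1e-12)
        assert p.kgb_bounds[0] < 10**p.log_kgb < p.kgb_bounds[1]
        assert 0 <= p.fraction_racemized <= 1
        assert p.risk_class == "high"
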