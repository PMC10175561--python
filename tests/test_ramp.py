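"""Tests for Arrhenius-profile construction and threshold analysis."""
import numpy as np
import pytest

import thermogate as tg
from thermogate.config import DetectionConfig
from thermogate.exceptions import (ExtrapolationError, InsufficientDataError,
                                   MissingReferenceError, NoActivationError,
                                   NoIntersectionError)
from thermogate.ramp import SegmentFit, q10_from_ratio

from conftest import make_exponential_trace, make_two_segment_profile


class TestToArrhenius:
    def test_single_sample_definition(self):
        tr = tg.TemperatureTrace("t", np.array([0.0]), np.array([25.0]),
                                 np.array([-100.0]))
        prof = tg.to_arrhenius(tr)
        assert prof.inv_temp_K[0] == pytest.approx(1.0 / 298.15, rel=1e-12)
        assert prof.log_current[0] == pytest.approx(np.log(100.0), rel=1e-12)

    def test_zero_current_samples_dropped_and_counted(self):
        tr = tg.TemperatureTrace("t", np.arange(4.0), np.array([20, 25, 30, 35.0]),
                                 np.array([-1.0, 0.0, -2.0, -3.0]))
        prof = tg.to_arrhenius(tr)
        assert len(prof) == 3
        assert prof.n_dropped == 1

    def test_pure_exponential_profile_is_linear(self):
        b = 12345.6
        tr = make_exponential_trace(a=2.0, b=b)
        prof = tg.to_arrhenius(tr)
        slope, intercept = np.polyfit(prof.inv_temp_K, prof.log_current, 1)
        assert slope == pytest.approx(-b, rel=1e-9)
        resid = prof.log_current - (intercept + slope * prof.inv_temp_K)
        assert np.max(np.abs(resid)) < 1e-9

    def test_ascending_in_inv_temp_regardless_of_ramp_direction(self):
        tr = tg.TemperatureTrace("t", np.arange(3.0), np.array([40, 30, 20.0]),
                                 np.array([-3.0, -2.0, -1.0]))
        prof = tg.to_arrhenius(tr)
        assert np.all(np.diff(prof.inv_temp_K) > 0)

    def test_insufficient_usable_samples(self):
        tr = tg.TemperatureTrace("t", np.arange(3.0), np.array([20, 25, 30.0]),
                                 np.zeros(3))
        with pytest.raises(InsufficientDataError):
            tg.to_arrhenius(tr)


class TestDetectThreshold:
    def test_exact_breakpoint_recovery(self):
        profile, breakpoint_c = make_two_segment_profile()
        res = tg.detect_threshold(profile, DetectionConfig(t_max_C=45.0))
        assert res.threshold_C == pytest.approx(breakpoint_c, abs=1e-6)
        assert breakpoint_c == pytest.approx(36.8527, abs=1e-3)  # 310 K

    def test_single_line_has_no_intersection(self):
        t_c = np.arange(20.0, 45.0, 0.25)
        x = 1.0 / (t_c + 273.15)
        prof = tg.ArrheniusProfile(np.sort(x), (5.0 - 3000.0 * np.sort(x)),
                                   np.arange(len(x)))
        with pytest.raises(NoIntersectionError):
            tg.detect_threshold(prof, DetectionConfig(t_max_C=45.0))

    def test_deterministic_given_profile_and_config(self):
        params = tg.GatingModelParams.from_t_half(36.0, noise_sd=0.03, seed=11)
        prof = tg.to_arrhenius(tg.simulate_heat_ramp(params))
        a = tg.detect_threshold(prof)
        b = tg.detect_threshold(prof)
        assert a.threshold_C == b.threshold_C
        assert a.steep == b.steep and a.baseline == b.baseline

    def test_t_max_cap_limits_analysed_range(self):
        params = tg.GatingModelParams.from_t_half(36.0)
        protocol = tg.RampProtocol(t_start_C=10.0, t_stop_C=50.0)
        prof = tg.to_arrhenius(tg.simulate_heat_ramp(params, protocol))
        res = tg.detect_threshold(prof, DetectionConfig(t_max_C=40.0))
        s, e = res.steep.index_range
        assert np.all(res.threshold_C <= 40.0)
        assert prof.temp_C[s:e].max() <= 40.0

    def test_thresholds_monotone_in_t_half(self):
        # same noise stream, T_half swept: detected thresholds must follow
        thresholds = []
        for t_half in np.arange(28.0, 44.1, 4.0):
            params = tg.GatingModelParams.from_t_half(t_half, noise_sd=0.02,
                                                      seed=5)
            protocol = tg.RampProtocol(t_start_C=10.0, t_stop_C=48.0)
            prof = tg.to_arrhenius(tg.simulate_heat_ramp(params, protocol))
            res = tg.detect_threshold(prof, DetectionConfig(t_max_C=48.0))
            thresholds.append(res.threshold_C)
        assert np.all(np.diff(thresholds) > 0)


class TestQ10:
    def test_zero_slope_means_no_temperature_dependence(self):
        fit = SegmentFit(slope=0.0, intercept=1.0, index_range=(0, 10), r2=1.0)
        assert tg.compute_q10(fit, 30.0) == pytest.approx(1.0)

    def test_hand_computed_value_at_150_kj_per_mol(self):
        # Ea = 150 kJ/mol <-> Arrhenius slope -18041.4 K; at 30 degC
        # Q10 = exp(18041.4 * 10 / (303.15 * 313.15)) ~ 6.69
        fit = SegmentFit(slope=-18041.4, intercept=0.0, index_range=(0, 10),
                         r2=1.0)
        expected = np.exp(18041.4 * 10.0 / (303.15 * 313.15))
        assert tg.compute_q10(fit, 30.0) == pytest.approx(expected, rel=1e-12)
        assert tg.compute_q10(fit, 30.0) == pytest.approx(6.69, rel=0.001)

    def test_slope_form_matches_ratio_form_on_pure_exponential(self):
        tr = make_exponential_trace(b=18041.3)
        prof = tg.to_arrhenius(tr)
        slope = np.polyfit(prof.inv_temp_K, prof.log_current, 1)[0]
        fit = SegmentFit(slope=slope, intercept=0.0,
                         index_range=(0, len(prof)), r2=1.0)
        q_slope = tg.compute_q10(fit, 30.0)
        q_ratio = q10_from_ratio(tr, 30.0)
        assert q_slope == pytest.approx(q_ratio, rel=0.01)


class TestHalfMaxActivation:
    def test_linear_rise_midpoint(self):
        t_c = np.arange(25.0, 41.0, 0.5)
        gated = np.interp(t_c, [30.0, 40.0], [0.0, 1000.0])
        tr = tg.TemperatureTrace("t", np.arange(len(t_c), dtype=float), t_c,
                                 -gated)
        assert tg.half_max_activation_temp(tr, None) == pytest.approx(35.0)

    def test_recovers_generating_t_half_with_negligible_leak(self):
        params = tg.GatingModelParams.from_t_half(35.0, leak_ref=0.0)
        protocol = tg.RampProtocol(t_start_C=10.0, t_stop_C=60.0)
        tr = tg.simulate_heat_ramp(params, protocol)
        t = tg.half_max_activation_temp(tr, None)
        assert t == pytest.approx(35.0, abs=0.25)  # grid resolution

    def test_interpolation_error_below_quarter_degree(self):
        params = tg.GatingModelParams.from_t_half(35.0, leak_ref=0.0)
        protocol = tg.RampProtocol(t_start_C=10.0, t_stop_C=60.0,
                                   rate_C_per_s=0.5, sample_hz=1.0)  # 0.5 degC
        tr = tg.simulate_heat_ramp(params, protocol)
        assert abs(tg.half_max_activation_temp(tr, None) - 35.0) < 0.25

    def test_no_activation_error(self):
        t_c = np.arange(20.0, 30.0, 0.5)
        tr = tg.TemperatureTrace("t", np.arange(len(t_c), dtype=float), t_c,
                                 -np.full(len(t_c), 10.0))
        baseline = SegmentFit(slope=0.0, intercept=np.log(20.0),
                              index_range=(0, 5), r2=1.0)
        with pytest.raises(NoActivationError):
            tg.half_max_activation_temp(tr, baseline)


class TestCurrentAtTemperature:
    def test_simple_ratio(self):
        t_c = np.arange(35.0, 41.0, 0.5)
        tr = tg.TemperatureTrace("t", np.arange(len(t_c), dtype=float), t_c,
                                 -np.full(len(t_c), 2000.0),
                                 i_capsaicin_nA=4000.0)
        assert tg.current_at_temperature(tr, 40.0) == pytest.approx(0.5)

    def test_linear_interpolation_between_samples(self):
        tr = tg.TemperatureTrace("t", np.array([0.0, 1.0]),
                                 np.array([39.8, 40.2]),
                                 np.array([-900.0, -1100.0]),
                                 i_capsaicin_nA=1000.0)
        assert tg.current_at_temperature(tr, 40.0) == pytest.approx(1.0)

    def test_missing_reference_and_extrapolation_errors(self):
        tr = tg.TemperatureTrace("t", np.array([0.0, 1.0]),
                                 np.array([30.0, 35.0]),
                                 np.array([-1.0, -2.0]))
        with pytest.raises(MissingReferenceError):
            tg.current_at_temperature(tr, 32.0)
        tr2 = tg.TemperatureTrace("t", np.array([0.0, 1.0]),
                                  np.array([30.0, 35.0]),
                                  np.array([-1.0, -2.0]), i_capsaicin_nA=10.0)
        with pytest.raises(ExtrapolationError):
            tg.current_at_temperature(tr2, 40.0)


class TestAnalyzeTrace:
    def test_threshold_below_half_max_on_simulated_traces(self):
        for t_half in (30.0, 34.0, 38.0):
            for seed in range(3):
                params = tg.GatingModelParams.from_t_half(
                    t_half, noise_sd=0.02, seed=seed)
                res = tg.analyze_trace(tg.simulate_heat_ramp(params))
                assert res.t_half_act_C is not None
                assert res.threshold_C <= res.t_half_act_C

    def test_full_result_fields_populated(self, default_params):
        res = tg.analyze_trace(tg.simulate_heat_ramp(default_params))
        assert res.q10 is not None and res.q10 > 1
        assert res.i_at_probe_norm is not None
        assert 0 < res.i_at_probe_norm < 2
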