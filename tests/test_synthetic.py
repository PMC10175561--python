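"""Unit and property tests for the synthetic-data generator."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thermogate as tg
from thermogate.exceptions import DomainError


class TestOpenProbability:
    def test_half_open_at_t_half(self, default_params):
        p = tg.open_probability(default_params.t_half_K, default_params)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_value(self):
        # direct evaluation of 1/(1 + exp((dH - T*dS)/(R*T)))
        params = tg.GatingModelParams(dH=200.0, dS=0.6536)
        assert tg.open_probability(300.0, params) == pytest.approx(0.172, abs=5e-4)

    def test_large_dh_approaches_step(self):
        t_half = 309.15
        sharp = tg.GatingModelParams(dH=20000.0, dS=20000.0 / t_half)
        assert tg.open_probability(t_half - 1.0, sharp) < 1e-10
        assert tg.open_probability(t_half + 1.0, sharp) > 1 - 1e-10

    def test_nonpositive_temperature_rejected(self, default_params):
        with pytest.raises(DomainError):
            tg.open_probability(0.0, default_params)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(dh=st.floats(20.0, 800.0), t_half_c=st.floats(5.0, 95.0),
           t1=st.floats(275.0, 370.0), dt=st.floats(1e-3, 50.0))
    def test_monotone_in_temperature(self, dh, t_half_c, t1, dt):
        params = tg.GatingModelParams.from_t_half(t_half_c, dH=dh)
        assert (tg.open_probability(t1 + dt, params)
                >= tg.open_probability(t1, params))


class TestHeatRamp:
    def test_cold_region_is_leak_only(self):
        params = tg.GatingModelParams.from_t_half(40.0)
        tr = tg.simulate_heat_ramp(params)
        cold = tr.temp_C <= 12.0
        leak = params.leak_ref * params.q10_leak ** ((tr.temp_C[cold] - 25) / 10)
        gated = np.abs(tr.current_nA[cold]) - leak
        assert np.all(gated < 0.01 * params.i_max)

    def test_seed_determinism(self, default_params):
        params = tg.GatingModelParams.from_t_half(36.0, noise_sd=0.05, seed=42)
        a = tg.simulate_heat_ramp(params)
        b = tg.simulate_heat_ramp(params)
        assert np.array_equal(a.current_nA, b.current_nA)
        c = tg.simulate_heat_ramp(
            tg.GatingModelParams.from_t_half(36.0, noise_sd=0.05, seed=43))
        assert not np.array_equal(a.current_nA, c.current_nA)

    def test_inward_sign_convention(self, default_params):
        tr = tg.simulate_heat_ramp(default_params)
        assert np.all(tr.current_nA < 0)

    def test_low_occupancy_arrhenius_slope_is_minus_dh_over_r(self):
        # ln(gated) vs 1/T has slope -dH/R where P < 0.05 (van't Hoff limit)
        params = tg.GatingModelParams.from_t_half(40.0, leak_ref=0.0)
        tr = tg.simulate_heat_ramp(params)
        t_k = tr.temp_C + 273.15
        p = tg.open_probability(t_k, params)
        sel = p < 0.05
        slope = np.polyfit(1.0 / t_k[sel], np.log(np.abs(tr.current_nA[sel])), 1)[0]
        expected = -params.dH * 1000.0 / 8.314462618
        assert slope == pytest.approx(expected, rel=0.02)

    def test_noiseless_magnitude_monotone_with_temperature(self, default_params):
        tr = tg.simulate_heat_ramp(default_params)
        assert np.all(np.diff(np.abs(tr.current_nA)) >= 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(DomainError):
            tg.GatingModelParams(dH=-1.0, dS=0.5)
        with pytest.raises(DomainError):
            tg.GatingModelParams(dH=250.0, dS=2.0)  # T_half = 125 K


class TestDoseResponse:
    def test_midpoint_and_zero(self):
        assert tg.hill_response(1.0, 1.0, 2.0, 10.0) == pytest.approx(5.0)
        assert tg.hill_response(0.0, 1.0, 2.0, 10.0) == 0.0

    def test_closed_form_nine_tenths(self):
        # ec50 = 1 uM, n = 2, C = 3 uM -> 9/(1+9) of r_max
        assert tg.hill_response(3.0, 1.0, 2.0, 1.0) == pytest.approx(0.9)

    def test_table_shape_and_determinism(self):
        df = tg.simulate_dose_response(1.0, 2.0, 1.0, [0.1, 1, 10],
                                       noise_sd=0.05, seed=3, n_replicates=4)
        assert list(df.columns) == ["construct", "stimulus_kind", "dose",
                                    "replicate", "response"]
        assert len(df) == 12
        df2 = tg.simulate_dose_response(1.0, 2.0, 1.0, [0.1, 1, 10],
                                        noise_sd=0.05, seed=3, n_replicates=4)
        assert df.equals(df2)

    def test_acid_uses_proton_concentration(self):
        # pH 6 -> [H+] = 1e-6 M; with ec50 = 1e-6 M the response is half-max
        df = tg.simulate_dose_response(1e-6, 1.0, 1.0, [6.0, 5.0, 7.0],
                                       stimulus_kind="acid")
        at_ph6 = df.loc[df.dose == 6.0, "response"].iloc[0]
        assert at_ph6 == pytest.approx(0.5)

    def test_empty_doses_rejected(self):
        with pytest.raises(DomainError):
            tg.simulate_dose_response(1.0, 1.0, 1.0, [])


class TestMeltCurve:
    def test_midpoint_fluorescence_at_tm(self):
        c = tg.simulate_melt_curve(32.0, f_native=1000.0, f_unfolded=5000.0)
        at_tm = np.interp(32.0, c.temp_C, c.fluorescence)
        assert at_tm == pytest.approx(3000.0, abs=1.0)

    def test_native_plateau_far_below_tm(self):
        c = tg.simulate_melt_curve(60.0, dH_unfold=800.0, f_native=1000.0,
                                   f_unfolded=5000.0)
        assert c.fluorescence[c.temp_C < 30].max() == pytest.approx(1000.0, abs=1.0)

    def test_seeded_noise_reproducible(self):
        a = tg.simulate_melt_curve(32.0, noise_sd=0.02, seed=9)
        b = tg.simulate_melt_curve(32.0, noise_sd=0.02, seed=9)
        assert np.array_equal(a.fluorescence, b.fluorescence)

    def test_grid_must_cover_reference(self):
        with pytest.raises(DomainError):
            tg.simulate_melt_curve(50.0, grid=np.arange(30.0, 95.0, 0.5))


class TestMutantPanel:
    def test_noiseless_panel_is_collinear(self):
        panel = tg.simulate_mutant_panel(10, 35.0, -1.5, (-2, 4), seed=0)
        r = tg.correlate_ddg_threshold(panel).r
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_zero_slope_gives_near_zero_mean_correlation(self):
        rs = [tg.correlate_ddg_threshold(
                tg.simulate_mutant_panel(16, 35.0, 0.0, (-2, 4),
                                         noise_sd=1.0, seed=s)).r
              for s in range(100)]
        assert abs(np.mean(rs)) < 0.1

    def test_degenerate_range_flags_warning(self):
        panel = tg.simulate_mutant_panel(5, 35.0, -1.0, (1.0, 1.0),
                                         noise_sd=0.5, seed=0)
        assert panel.attrs["warnings"]
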