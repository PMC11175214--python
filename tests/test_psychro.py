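import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fenceline.io import MOX_COLUMNS, SensorStream
from fenceline.psychro import (
    BaselineModel,
    absolute_humidity,
    compensate_stream,
    fit_baselines,
    fit_dynamic_baseline,
    fit_static_baseline,
    normalize_signal,
    reference_resistance,
    saturation_vapour_pressure,
)
from fenceline.simulate import SimConfig, simulate_ambient


class TestSaturationPressure:
    def test_steam_table_anchor_20C(self):
        # steam tables: 2.339 kPa at 20 degC
        assert saturation_vapour_pressure(293.15) == pytest.approx(2339, rel=0.01)

    def test_triple_point_anchor(self):
        assert saturation_vapour_pressure(273.16) == pytest.approx(611.7, rel=0.01)

    @given(st.floats(min_value=255.0, max_value=345.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_temperature(self, t):
        assert saturation_vapour_pressure(t + 1.0) > saturation_vapour_pressure(t)

    def test_out_of_band_temperature_rejected(self):
        with pytest.raises(ValueError):
            saturation_vapour_pressure(200.0)


class TestAbsoluteHumidity:
    def test_reference_value_50pct_20C(self):
        # psychrometric tables: ~8.6-8.7 g/m^3 at 50% RH, 20 degC
        assert absolute_humidity(50.0, 293.15) == pytest.approx(8.65, rel=0.01)

    def test_zero_humidity(self):
        assert absolute_humidity(0.0, 293.15) == 0.0

    @given(
        st.floats(min_value=1.0, max_value=50.0),
        st.floats(min_value=260.0, max_value=340.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_exactly_linear_in_rh(self, rh, t):
        assert absolute_humidity(2 * rh, t) == pytest.approx(
            2 * absolute_humidity(rh, t), rel=1e-12
        )

    def test_increasing_in_temperature_at_fixed_rh(self):
        t = np.linspace(265, 340, 50)
        ah = absolute_humidity(np.full_like(t, 50.0), t)
        assert np.all(np.diff(ah) > 0)

    def test_negative_rh_rejected(self):
        with pytest.raises(ValueError):
            absolute_humidity(-1.0, 293.15)


class TestBaselines:
    def test_static_reference_is_mean(self):
        model = fit_static_baseline(np.array([90e3, 110e3, 90e3, 110e3]))
        assert model.static_ref == pytest.approx(100e3)

    def test_static_reference_matches_brute_force_mean(self, sim_config):
        stream = simulate_ambient(sim_config, duration_s=3600.0, seed=5)
        model = fit_static_baseline(stream.data["mox1_ohm"].to_numpy())
        assert model.static_ref == pytest.approx(
            float(np.mean(stream.data["mox1_ohm"])), rel=1e-12
        )

    def test_noiseless_line_recovered_exactly(self):
        ah = np.linspace(5, 18, 50)
        y = 100e3 - 2e3 * ah
        model = fit_dynamic_baseline(y, ah, degree=1)
        np.testing.assert_allclose(model.coefficients, [100e3, -2e3], rtol=1e-9)

    def test_noiseless_cubic_auto_selects_degree_three(self):
        ah = np.linspace(5, 18, 200)
        coeffs = np.array([120e3, -3e3, 50.0, -1.2])
        y = np.polynomial.polynomial.polyval(ah, coeffs)
        model = fit_dynamic_baseline(y, ah)  # automatic degree
        assert len(model.coefficients) == 4
        np.testing.assert_allclose(model.coefficients, coeffs, rtol=1e-6)

    def test_flat_noise_auto_selects_degree_one(self, rng):
        ah = np.linspace(5, 18, 300)
        y = 100e3 + 500.0 * rng.standard_normal(300)
        model = fit_dynamic_baseline(y, ah)
        assert len(model.coefficients) == 2
        # slope indistinguishable from zero at the noise scale
        assert abs(model.coefficients[1]) * 13 < 5 * 500.0

    def test_collinear_ah_rejected(self):
        with pytest.raises(ValueError, match="distinct AH"):
            fit_dynamic_baseline([1.0, 2.0, 3.0], [10.0, 10.0, 10.0])

    def test_reference_evaluation(self):
        static = BaselineModel(sensor_id="s", mode="static", static_ref=1e5)
        assert reference_resistance(static, 12.3) == 1e5
        dynamic = BaselineModel(
            sensor_id="s",
            mode="dynamic",
            coefficients=[100000.0, -2000.0],
            ah_range=(0.0, 20.0),
        )
        assert reference_resistance(dynamic, 10.0) == pytest.approx(80000.0)

    def test_extrapolation_clamps_with_warning(self):
        dynamic = BaselineModel(
            sensor_id="s",
            mode="dynamic",
            coefficients=[100000.0, -2000.0],
            ah_range=(5.0, 10.0),
        )
        with pytest.warns(UserWarning, match="clamping"):
            val = reference_resistance(dynamic, 20.0)
        assert val == pytest.approx(80000.0)  # clamped to AH=10

    def test_raw_mode_has_no_reference(self):
        raw = BaselineModel(sensor_id="s", mode="none")
        with pytest.raises(ValueError):
            reference_resistance(raw, 10.0)


class TestNormalization:
    def test_zero_when_at_reference(self):
        assert normalize_signal(50e3, 50e3) == 0.0

    def test_printed_form_uses_raw_denominator(self):
        # (y - y_ref) / y, evaluated as printed: (2 - 1) / 2
        assert normalize_signal(2.0, 1.0) == pytest.approx(0.5)

    def test_reference_denominator_variant(self):
        assert normalize_signal(2.0, 1.0, denominator="y_ref") == pytest.approx(1.0)

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError):
            normalize_signal(0.0, 1.0)


class TestCompensation:
    def test_raw_mode_is_identity(self, small_campaign):
        stream, _ = small_campaign
        out = compensate_stream(stream, None, mode="CA")
        pd.testing.assert_frame_equal(out.data, stream.data)

    def test_static_mode_zeroes_constant_stream(self):
        n = 60
        ts = pd.Timestamp("2022-02-01T00:00:00+00:00") + pd.to_timedelta(
            np.arange(n) * 10, unit="s"
        )
        df = pd.DataFrame(
            {
                "timestamp": ts,
                "mox1_ohm": 2e5, "mox2_ohm": 1.5e5,
                "mox3_ohm": 3e5, "mox4_ohm": 1.8e5,
                "ec_h2s": 0.0, "ec_nh3": 0.0, "pid": 20.0,
                "temp_c": 18.0, "rh_pct": 60.0,
            }
        )
        stream = SensorStream(df)
        baselines = fit_baselines(stream, mode="CB")
        out = compensate_stream(stream, baselines, mode="CB")
        for c in MOX_COLUMNS:
            np.testing.assert_allclose(out.data[c], 0.0, atol=1e-12)

    def test_dynamic_mode_matches_elementwise_oracle(self, sim_config):
        stream = simulate_ambient(sim_config, duration_s=7200.0, seed=9)
        baselines = fit_baselines(stream, mode="CC")
        out = compensate_stream(stream, baselines, mode="CC")
        from fenceline.psychro import absolute_humidity_c

        ah = absolute_humidity_c(
            stream.data["rh_pct"].to_numpy(), stream.data["temp_c"].to_numpy()
        )
        for c in MOX_COLUMNS:
            y = stream.data[c].to_numpy()
            y_ref = np.polynomial.polynomial.polyval(
                np.clip(ah, *baselines[c].ah_range), baselines[c].coefficients
            )
            np.testing.assert_allclose(out.data[c], (y - y_ref) / y, rtol=1e-10)

    def test_dynamic_compensation_removes_humidity_variance(self, sim_config):
        """On odourless air with AH swings, the compensated signal varies far
        less than the raw humidity-driven baseline excursion."""
        stream = simulate_ambient(sim_config, duration_s=21600.0, seed=13)
        baselines = fit_baselines(stream, mode="CC")
        out = compensate_stream(stream, baselines, mode="CC")
        raw_rel_sd = float(
            stream.data["mox1_ohm"].std() / stream.data["mox1_ohm"].mean()
        )
        comp_sd = float(out.data["mox1_ohm"].std())
        assert comp_sd < 0.2 * raw_rel_sd

    def test_missing_baseline_rejected(self, small_campaign):
        stream, _ = small_campaign
        with pytest.raises(ValueError, match="baseline"):
            compensate_stream(stream, {}, mode="CC")
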