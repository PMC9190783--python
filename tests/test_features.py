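"""Per-feature definitions, the feature-major layout, and scaling laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from emglove.features import (
    FEATURE_NAMES,
    FeatureConfig,
    extract_features,
    feature_names,
    mav,
    read_features,
    rms,
    ssc,
    ssi,
    var,
    wl,
    write_features,
    zc,
)
from emglove.signal import Window

NO_DEADZONE = FeatureConfig(zc_threshold=0.0, ssc_threshold=0.0)

waveforms = arrays(
    float, st.integers(3, 80), elements=st.floats(-1.0, 1.0, allow_nan=False, width=32)
)


class TestFeatureDefinitions:
    @pytest.mark.parametrize(
        "x,expected",
        [([0.5, -0.5, 0.5, -0.5], 0.5), ([0.0, 0.0, 0.0], 0.0)],
    )
    def test_mav(self, x, expected):
        assert mav(x) == pytest.approx(expected)

    @pytest.mark.parametrize("x,expected", [([1, -1, 1, -1], 1.0), ([0, 0, 0], 0.0)])
    def test_rms(self, x, expected):
        assert rms(x) == pytest.approx(expected)

    def test_var_zero_mean_convention(self):
        assert var([1, -1, 1, -1]) == pytest.approx(4.0 / 3.0)
        assert var([0, 0, 0, 0]) == 0.0

    def test_var_conventions_agree_on_mean_zero_input(self):
        x = np.array([0.3, -0.3, 0.5, -0.5])
        assert var(x) == pytest.approx(var(x, FeatureConfig(var_convention="centered")))

    def test_ssi(self):
        assert ssi([1, 1, 1, 1]) == pytest.approx(4.0)
        assert ssi([0.5]) == pytest.approx(0.25)

    @settings(deadline=None, max_examples=25)
    @given(waveforms)
    def test_ssi_equals_n_times_rms_squared(self, x):
        assert ssi(x) == pytest.approx(len(x) * rms(x) ** 2, abs=1e-9)

    @pytest.mark.parametrize(
        "x,cfg,expected",
        [
            ([1, -1, 1, -1], NO_DEADZONE, 3),
            ([1, 1, 1], FeatureConfig(), 0),
            ([0.004, -0.004], FeatureConfig(), 0),  # jump below the deadzone
            ([0.004, -0.004], NO_DEADZONE, 1),
        ],
    )
    def test_zc(self, x, cfg, expected):
        assert zc(x, cfg) == expected

    def test_wl(self):
        assert wl([0, 1, 0, 1]) == pytest.approx(3.0)
        assert wl([0.7] * 10) == 0.0

    @settings(deadline=None, max_examples=25)
    @given(waveforms)
    def test_wl_triangle_inequality(self, x):
        assert wl(x) >= abs(x[-1] - x[0]) - 1e-12

    @settings(deadline=None, max_examples=25)
    @given(waveforms)
    def test_mav_bounded_by_peak_and_rms(self, x):
        assert mav(x) <= np.abs(x).max() + 1e-12
        assert rms(x) >= mav(x) - 1e-12  # power-mean inequality

    @pytest.mark.parametrize(
        "x,cfg,expected",
        [
            ([0, 1, 0, 1, 0], NO_DEADZONE, 3),
            (np.linspace(-1, 1, 20), FeatureConfig(), 0),
        ],
    )
    def test_ssc(self, x, cfg, expected):
        assert ssc(x, cfg) == expected

    def test_ssc_sine_two_periods_matches_brute_force(self):
        # phase offset keeps the extrema off the exact midpoint between samples
        x = np.sin(2 * np.pi * 2 * np.arange(60) / 60 + 0.3)
        cfg = FeatureConfig()
        brute = sum(
            1
            for i in range(1, 59)
            if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) >= cfg.ssc_threshold
        )
        assert brute == 4  # two maxima + two minima
        assert ssc(x, cfg) == brute

    def test_short_inputs_raise(self):
        with pytest.raises(ValueError):
            mav([])
        with pytest.raises(ValueError):
            zc([0.5])
        with pytest.raises(ValueError):
            ssc([0.5, -0.5])


class TestFeatureVectorLayout:
    def test_feature_major_layout_matches_per_feature_calls(self):
        rng = np.random.default_rng(7)
        w = Window(data=rng.uniform(-1, 1, (8, 60)))
        cfg = FeatureConfig()
        fv = extract_features(w, cfg)
        assert fv.values.shape == (56,)
        funcs = {
            "mav": lambda x: mav(x), "rms": lambda x: rms(x),
            "var": lambda x: var(x, cfg), "ssi": lambda x: ssi(x),
            "zc": lambda x: zc(x, cfg), "wl": lambda x: wl(x),
            "ssc": lambda x: ssc(x, cfg),
        }
        for fi, name in enumerate(FEATURE_NAMES):
            for ch in range(8):
                assert fv.values[fi * 8 + ch] == pytest.approx(
                    funcs[name](w.data[ch])
                ), f"{name} ch{ch + 1}"
        # spot check the documented layout: position 9 is RMS of channel 1
        assert fv.values[8] == pytest.approx(rms(w.data[0]))

    def test_all_zero_window_gives_all_zero_vector(self):
        fv = extract_features(Window(data=np.zeros((8, 60))))
        np.testing.assert_array_equal(fv.values, np.zeros(56))

    def test_sixteen_channel_window_gives_112_values(self):
        rng = np.random.default_rng(3)
        fv = extract_features(Window(data=rng.uniform(-1, 1, (16, 60))))
        assert fv.values.shape == (7 * 16,)

    def test_channel_count_mismatch_raises(self):
        with pytest.raises(ValueError, match="channels"):
            extract_features(Window(data=np.zeros((4, 60))), channel_count=8)

    def test_rectification_invariance_of_magnitude_features(self):
        rng = np.random.default_rng(5)
        w = Window(data=rng.uniform(-1, 1, (8, 60)))
        wr = Window(data=np.abs(w.data))
        fv, fvr = extract_features(w), extract_features(wr)
        for fi, name in enumerate(FEATURE_NAMES):
            if name in ("mav", "rms", "var", "ssi"):
                np.testing.assert_allclose(
                    fv.values[fi * 8 : (fi + 1) * 8], fvr.values[fi * 8 : (fi + 1) * 8]
                )

    @settings(deadline=None, max_examples=20)
    @given(st.floats(0.1, 8.0))
    def test_amplitude_scaling_laws(self, c):
        rng = np.random.default_rng(11)
        data = rng.uniform(-0.1, 0.1, (8, 60))
        cfg = FeatureConfig(zc_threshold=0.01, ssc_threshold=0.0)
        cfg_scaled = FeatureConfig(zc_threshold=0.01 * c, ssc_threshold=0.0)
        base = extract_features(Window(data=data), cfg).values
        scaled = extract_features(Window(data=np.clip(c * data, -1, 1)), cfg_scaled).values
        for fi, name in enumerate(FEATURE_NAMES):
            sl = slice(fi * 8, (fi + 1) * 8)
            if name in ("mav", "rms", "wl"):
                np.testing.assert_allclose(scaled[sl], c * base[sl], rtol=1e-9)
            elif name in ("var", "ssi"):
                np.testing.assert_allclose(scaled[sl], c * c * base[sl], rtol=1e-9)
            elif name == "zc":
                np.testing.assert_array_equal(scaled[sl], base[sl])


class TestFeatureIO:
    def test_csv_round_trip_with_labels(self, tmp_path):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 1, (10, 56))
        y = rng.integers(0, 6, 10)
        path = tmp_path / "features.csv"
        write_features(path, X, y)
        X2, y2 = read_features(path)
        np.testing.assert_allclose(X2, X, atol=1e-10)
        np.testing.assert_array_equal(y2, y)
        assert feature_names(8)[8] == "rms_ch1"
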