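import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from skelquant.errors import (
    ConfigError,
    InputError,
    SeriesTooShortError,
    UndefinedACFError,
)
from skelquant.skeleton_geometry import PARAMETER_NAMES, ParameterSeries
from skelquant.timeseries_features import (
    FEATURE_NAMES,
    AnalysisConfig,
    acf_lag,
    averaged_variance,
    difference,
    extract_features,
    first_acf_differenced,
    first_acf_original,
)

from oracles import acf_lag1_brute, averaged_variance_brute


def ar1(rng, T, phi, sd=1.0):
    u = np.empty(T)
    u[0] = rng.normal() * sd
    innov = sd * np.sqrt(1 - phi * phi)
    eps = rng.normal(size=T - 1) * innov
    for t in range(1, T):
        u[t] = phi * u[t - 1] + eps[t - 1]
    return u


def make_series_set(rng, T=200):
    return [
        ParameterSeries(name, rng.normal(size=T).cumsum(), "s1", "before")
        for name in PARAMETER_NAMES
    ]


class TestDifference:
    def test_direct_example(self):
        np.testing.assert_array_equal(difference([5, 2, 7]), [-3, 5])

    def test_constant_series(self):
        np.testing.assert_array_equal(difference([4.0] * 4), [0, 0, 0])

    def test_too_short(self):
        with pytest.raises(SeriesTooShortError):
            difference([1.0])

    @given(arrays(np.float64, st.integers(2, 50),
                  elements=st.floats(-1e6, 1e6)))
    def test_cumsum_inverse(self, s):
        recovered = np.concatenate([[s[0]], s[0] + np.cumsum(difference(s))])
        np.testing.assert_allclose(recovered, s, atol=1e-6)


class TestAcfLag:
    def test_linear_ramp_exactly_one(self):
        assert acf_lag(np.arange(1.0, 101.0), 1) == 1.0

    def test_alternating_exactly_minus_one(self):
        assert acf_lag(np.tile([1.0, -1.0], 50), 1) == -1.0

    def test_constant_series_undefined(self):
        with pytest.raises(UndefinedACFError):
            acf_lag(np.full(50, 3.0), 1)

    def test_too_short(self):
        with pytest.raises(SeriesTooShortError):
            acf_lag([1.0, 2.0], 1)

    def test_three_points_two_pair_degeneracy(self):
        # two overlapping pairs always correlate to exactly +-1
        assert acf_lag([1.0, 2.0, 4.0], 1) == 1.0
        assert acf_lag([1.0, 2.0, 0.0], 1) == -1.0

    def test_ar1_recovers_coefficient(self):
        rng = np.random.default_rng(42)
        s = ar1(rng, 10_000, 0.8)
        est = acf_lag(s, 1)
        assert est == pytest.approx(0.8, abs=0.03)
        assert est == pytest.approx(acf_lag1_brute(s), abs=1e-12)

    def test_white_noise_near_zero(self):
        rng = np.random.default_rng(7)
        assert abs(first_acf_original(rng.normal(size=10_000))) < 0.05

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = rng.normal(size=rng.integers(5, 200))
            assert acf_lag(s, 1) == pytest.approx(acf_lag1_brute(s), abs=1e-12)

    def test_higher_lag(self):
        rng = np.random.default_rng(3)
        s = ar1(rng, 10_000, 0.8)
        # stationary AR(1): lag-2 autocorrelation is phi^2
        assert acf_lag(s, 2) == pytest.approx(0.64, abs=0.05)

    def test_stationary_estimator_close_on_long_series(self):
        rng = np.random.default_rng(12)
        s = ar1(rng, 5_000, 0.6)
        assert acf_lag(s, 1, estimator="stationary") == pytest.approx(
            acf_lag(s, 1), abs=0.01
        )

    @settings(deadline=None)
    @given(arrays(np.float64, st.integers(4, 100),
                  elements=st.floats(-1e3, 1e3)),
           st.floats(0.01, 100.0), st.floats(-1e3, 1e3))
    def test_bounded_and_affine_invariant(self, s, a, b):
        try:
            r = acf_lag(s, 1)
        except UndefinedACFError:
            return
        assert -1.0 <= r <= 1.0
        # guard against catastrophic cancellation: the shift must not drown
        # the series' spread in float rounding
        assume(np.ptp(a * s) > 1e-9 * max(1.0, abs(b)))
        assert acf_lag(a * s + b, 1) == pytest.approx(r, abs=1e-6)


class TestDifferencedAcf:
    def test_ramp_differenced_is_constant_undefined(self):
        with pytest.raises(UndefinedACFError):
            first_acf_differenced(np.arange(100.0))

    def test_too_short(self):
        with pytest.raises(SeriesTooShortError):
            first_acf_differenced([1.0, 2.0, 1.0])

    @pytest.mark.parametrize("phi", [0.0, 0.5, 0.8])
    def test_ar1_closed_form(self, phi):
        # differenced stationary AR(1) has lag-1 autocorrelation -(1-phi)/2
        rng = np.random.default_rng(int(phi * 10) + 1)
        s = ar1(rng, 20_000, phi)
        expected = -(1 - phi) / 2
        est = first_acf_differenced(s)
        assert est == pytest.approx(expected, abs=0.03)
        assert est == pytest.approx(acf_lag1_brute(np.diff(s)), abs=1e-12)


class TestAveragedVariance:
    def test_two_windows(self):
        assert averaged_variance([0, 2, 0, 2], 2) == 1.0

    def test_remainder_dropped(self):
        assert averaged_variance([1, 1, 2, 2, 9], 2) == 0.0

    def test_affine_property(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=97)
        assert averaged_variance(3 * s + 7, 10) == pytest.approx(
            9 * averaged_variance(s, 10), rel=1e-12
        )

    def test_window_equal_to_length_is_population_variance(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=64)
        assert averaged_variance(s, 64) == pytest.approx(s.var(ddof=0), rel=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            s = rng.normal(size=rng.integers(10, 150))
            w = int(rng.integers(2, 30))
            if len(s) < w:
                continue
            assert averaged_variance(s, w) == pytest.approx(
                averaged_variance_brute(list(s), w), rel=1e-10
            )

    def test_too_short(self):
        with pytest.raises(SeriesTooShortError):
            averaged_variance([1.0, 2.0], 5)

    def test_window_one_disallowed(self):
        with pytest.raises(ConfigError):
            averaged_variance([1.0, 2.0], 1)


class TestAnalysisConfig:
    def test_defaults(self):
        cfg = AnalysisConfig()
        assert cfg.window_size == 30 and cfg.lag == 1

    @pytest.mark.parametrize("kwargs", [
        {"window_size": 1}, {"lag": 0}, {"acf_estimator": "burg"},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ConfigError):
            AnalysisConfig(**kwargs)


class TestExtractFeatures:
    def test_33_features_22_acf(self):
        rng = np.random.default_rng(1)
        fv = extract_features(make_series_set(rng), AnalysisConfig())
        assert len(fv) == 33
        assert tuple(fv.values) == FEATURE_NAMES
        acf = [n for n in fv.values if n.startswith("acf_")]
        assert len(acf) == 22
        assert all(np.isfinite(v) for v in fv.values.values())
        for n, v in fv.values.items():
            if n.startswith("acf_"):
                assert -1.0 <= v <= 1.0
            else:
                assert v >= 0.0

    def test_static_recording_avgvar_zero_acf_missing(self):
        series = [
            ParameterSeries(name, np.full(120, 10.0), "s1", "before")
            for name in PARAMETER_NAMES
        ]
        with pytest.warns(UserWarning, match="undefined"):
            fv = extract_features(series, AnalysisConfig())
        for name, v in fv.values.items():
            if name.startswith("avgvar_"):
                assert v == 0.0
            else:
                assert np.isnan(v)

    def test_wrong_series_count_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(InputError):
            extract_features(make_series_set(rng)[:10], AnalysisConfig())

    def test_series_scaling_quadruples_avgvar_keeps_acf(self):
        rng = np.random.default_rng(3)
        series = make_series_set(rng)
        doubled = [
            ParameterSeries(s.parameter_name, 2.0 * s.values, s.subject_id,
                            s.session_label)
            for s in series
        ]
        base = extract_features(series, AnalysisConfig())
        big = extract_features(doubled, AnalysisConfig())
        for name in FEATURE_NAMES:
            if name.startswith("avgvar_"):
                assert big.values[name] == pytest.approx(
                    4.0 * base.values[name], rel=1e-12
                )
            else:
                assert big.values[name] == pytest.approx(
                    base.values[name], abs=1e-12
                )

    def test_keypoint_amplitude_doubling_quadruples_length_avgvar(self):
        # Monte-Carlo through the geometry stage: pure-jitter motion, lengths
        # respond (approximately) linearly to displacement amplitude.
        from skelquant.pipeline import features_for_sequence
        from skelquant.synthetic_motion import MotionConfig, generate_sequence

        ratios = []
        for rep in range(8):
            fvs = {}
            for sd in (1.0, 2.0):
                seq = generate_sequence(
                    MotionConfig(T=600, seed=500 + rep, jitter_sd=sd,
                                 sway_amplitude=0.0, swivel_amplitude_deg=0.0)
                )
                fvs[sd] = features_for_sequence(seq)
            for name in FEATURE_NAMES:
                if name.startswith("avgvar_") and name.endswith("_length"):
                    ratios.append(fvs[2.0].values[name] / fvs[1.0].values[name])
        assert np.median(ratios) == pytest.approx(4.0, rel=0.25)

    def test_short_series_raises(self):
        series = [
            ParameterSeries(name, np.arange(10.0), "s1", "before")
            for name in PARAMETER_NAMES
        ]
        with pytest.raises(SeriesTooShortError):
            extract_features(series, AnalysisConfig(window_size=30))
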