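"""Feature battery: hand-computed values, counts, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import shoegait as sg
from shoegait.features import (META_COLUMNS, feature_columns,
                               sensor_of_feature)


def brute_force(name, x, y=None):
    """Independent plain-Python evaluation of each printed formula."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    if name == "mean":
        return mean
    if name == "maxvalue":
        return max(x)
    if name == "power":
        return sum(v * v for v in x) / n
    if name == "spectral_flux":
        return sum((x[i] - x[i - 1]) ** 2 for i in range(1, n))
    if name == "zerocrossing":
        return sum(1 for i in range(1, n) if x[i] * x[i - 1] < 0)
    sd = (sum((v - mean) ** 2 for v in x) / (n - 1)) ** 0.5
    if name == "std":
        return sd
    if name == "crest_factor":
        return max(x) / (sum(v * v for v in x) / (n - 1)) ** 0.5
    if name == "kurtosis":
        return sum((v - mean) ** 4 for v in x) / n / sd**4 - 3
    if name == "skewness":
        return sum(((v - mean) / sd) ** 3 for v in x) / n
    if name == "correlation":
        my = sum(y) / n
        sy = (sum((v - my) ** 2 for v in y) / (n - 1)) ** 0.5
        return (sum((a - mean) * (b - my) for a, b in zip(x, y))
                / ((n - 1) * sd * sy))
    raise ValueError(name)


class TestFeatureValues:
    @pytest.mark.parametrize("name,x,expected", [
        ("mean", [1, 2, 3], 2.0),
        ("std", [2, 2, 2], 0.0),
        ("power", [1, 2, 3], 14 / 3),
        ("spectral_flux", [0, 1, 0, 1], 3.0),
        ("zerocrossing", [1, -1, 1, -1], 3.0),
        # constant positive signal, N=4: max/RMS = sqrt((N-1)/N)
        ("crest_factor", [5, 5, 5, 5], np.sqrt(3) / 2),
        ("maxvalue", [-3, 7, 1], 7.0),
    ])
    def test_hand_computed_examples(self, name, x, expected):
        assert sg.feature_value(name, np.array(x, float)) == pytest.approx(expected)

    def test_self_correlation_is_one(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        assert sg.feature_value("correlation", x, x) == pytest.approx(1.0)

    def test_entropy_extremes(self):
        # all samples in one bin -> 0; uniform occupancy of 10 bins -> ln 10
        assert sg.feature_value("entropy", np.full(50, 3.0)) == 0.0
        x = np.concatenate([np.full(10, b + 0.5) for b in range(10)])
        assert sg.feature_value("entropy", x) == pytest.approx(np.log(10))

    @pytest.mark.parametrize("name", [
        "mean", "std", "power", "spectral_flux", "zerocrossing",
        "crest_factor", "kurtosis", "skewness", "correlation",
    ])
    def test_matches_brute_force_on_random_vectors(self, name):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(2.0, 3.0, rng.integers(5, 40))
            y = rng.normal(0.0, 1.0, x.size)
            got = sg.feature_value(name, x, y if name == "correlation" else None)
            assert got == pytest.approx(brute_force(name, x, y), rel=1e-10)

    def test_moments_agree_with_scipy(self):
        # independent oracle: scipy's biased moments with our normalisation
        rng = np.random.default_rng(4)
        x = rng.gamma(2.0, 1.5, 500)
        n = x.size
        sd = x.std(ddof=1)
        kurt = stats.moment(x, 4) / sd**4 - 3
        skew = stats.moment(x, 3) / sd**3
        assert sg.feature_value("kurtosis", x) == pytest.approx(kurt)
        assert sg.feature_value("skewness", x) == pytest.approx(skew)

    def test_table1_literal_variants(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        sd = x.std(ddof=1)
        lit = sg.feature_value("kurtosis", x, table1_literal=True)
        conv = sg.feature_value("kurtosis", x)
        assert lit + 3 == pytest.approx((conv + 3) * sd**2)

    def test_degenerate_segments_fall_back_to_zero(self):
        const = np.full(10, 2.0)
        for name in ("kurtosis", "skewness", "entropy"):
            assert sg.feature_value(name, const) == 0.0
        assert sg.feature_value("correlation", const, np.arange(10.0)) == 0.0

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            sg.feature_value("std", np.array([1.0]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        scale=st.floats(0.1, 50.0), shift=st.floats(-10.0, 10.0),
        seed=st.integers(0, 100),
    )
    def test_affine_invariance_and_scale_sensitivity(self, scale, shift, seed):
        """Correlation, kurtosis, skewness, entropy are invariant under
        positive affine maps; power and std are not."""
        rng = np.random.default_rng(seed)
        x = rng.normal(0.0, 1.0, 64)
        y = rng.normal(0.0, 1.0, 64)
        z = scale * x + shift
        for name in ("kurtosis", "skewness", "entropy"):
            assert sg.feature_value(name, z) == pytest.approx(
                sg.feature_value(name, x), rel=1e-8, abs=1e-8)
        assert sg.feature_value("correlation", z, y) == pytest.approx(
            sg.feature_value("correlation", x, y), rel=1e-8, abs=1e-8)
        # std scales with the gain: not invariant unless scale == 1
        assert sg.feature_value("std", z) == pytest.approx(
            scale * sg.feature_value("std", x), rel=1e-8)
        if abs(scale - 1.0) > 0.05:
            assert sg.feature_value("std", z) != pytest.approx(
                sg.feature_value("std", x), rel=1e-3)


class TestCorrelationPairs:
    @pytest.mark.parametrize("sensor,count", [
        ("pressure", 12), ("accelerometer", 6), ("gyroscope", 6),
    ])
    def test_within_shoe_pair_counts(self, sensor, count):
        assert len(sg.correlation_pairs(sensor_type=sensor)) == count

    def test_pairs_are_within_shoe(self):
        layout = sg.DEFAULT_LAYOUT
        for a, b in sg.correlation_pairs():
            assert layout.foot_of_channel(a) == layout.foot_of_channel(b)
            assert layout.sensor_of_channel(a) == layout.sensor_of_channel(b)


class TestFeatureTable:
    def test_full_battery_has_224_columns(self):
        assert len(feature_columns(include_discarded=True)) == 224

    def test_retained_battery_has_172_columns(self):
        assert len(feature_columns(include_discarded=False)) == 172

    def test_count_arithmetic_per_sensor(self):
        # correlations + retained stats x channels, per sensor type
        for sensor, expected in (("pressure", 76), ("accelerometer", 48),
                                 ("gyroscope", 48)):
            cols = [c for c in feature_columns(include_discarded=False)
                    if sensor_of_feature(c) == sensor]
            assert len(cols) == expected

    def test_built_table_shape_and_finiteness(self, cohort2):
        segments = sg.segment_cohort(cohort2, "stride")
        table = sg.build_feature_table(segments, cohort2)
        feats = [c for c in table.columns if c not in META_COLUMNS]
        assert len(feats) == 224
        assert np.isfinite(table[feats].to_numpy()).all()
        assert set(table["gait_class"]) == set(sg.GAIT_CLASSES)

    def test_column_order_deterministic(self, cohort2):
        segments = sg.segment_cohort(cohort2, "stride")[:3]
        a = sg.build_feature_table(segments, cohort2)
        b = sg.build_feature_table(segments, cohort2)
        assert list(a.columns) == list(b.columns)
        pd.testing.assert_frame_equal(a, b)

    def test_sensor_subset_column_counts(self, cohort2):
        segments = sg.segment_cohort(cohort2, "stride")[:5]
        table = sg.apply_discard_rule(sg.build_feature_table(segments, cohort2))
        ag = sg.select_sensor_columns(table, {"accelerometer", "gyroscope"})
        assert len([c for c in ag.columns if c not in META_COLUMNS]) == 96

    def test_unknown_recording_reference_raises(self, cohort2):
        segments = sg.segment_cohort(cohort2, "stride")[:1]
        with pytest.raises(KeyError):
            sg.build_feature_table(segments, [])
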