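"""Speed estimation, motion states, place clustering and daily mobility features."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from digiphen.geo import vincenty_distance
from digiphen.mobility import (
    AdaptiveKMeans,
    VARIANCE_FLOOR,
    adaptive_kmeans,
    classify_speed,
    classify_states,
    estimate_speeds,
    extract_mobility,
    location_variance,
    normalized_entropy,
)
from digiphen.types import SensorBundle

TZ = "America/Chicago"
M_PER_DEG_LAT = 111_194.9  # WGS84 mean, fine for metre-scale test tracks


def make_fixes(latlon, start="2017-01-02 15:00:00", cadence_s=60.0):
    ts = pd.to_datetime(start).tz_localize("UTC") + pd.to_timedelta(
        np.arange(len(latlon)) * cadence_s, unit="s")
    arr = np.asarray(latlon, dtype=float)
    return pd.DataFrame({"timestamp": ts, "latitude": arr[:, 0], "longitude": arr[:, 1]})


class TestEstimateSpeeds:
    def test_two_fixes_simple_arithmetic(self):
        # 100 m apart in 50 s -> 2.0 m/s, first fix inherits
        dlat = 100.0 / M_PER_DEG_LAT
        fixes = make_fixes([(29.7, -95.4), (29.7 + dlat, -95.4)], cadence_s=50)
        out = estimate_speeds(fixes)
        assert out["speed_mps"].iloc[1] == pytest.approx(2.0, rel=0.01)
        assert out["speed_mps"].iloc[0] == out["speed_mps"].iloc[1]

    def test_identical_coordinates_zero_speed(self):
        fixes = make_fixes([(29.7, -95.4)] * 3)
        out = estimate_speeds(fixes)
        assert (out["speed_mps"] == 0.0).all()

    def test_gap_splits_trace(self):
        fixes = make_fixes([(29.7, -95.4), (29.7, -95.39), (29.8, -95.3), (29.8, -95.29)])
        # push a 10-minute hole between rows 1 and 2
        fixes.loc[2:, "timestamp"] += pd.Timedelta(minutes=10)
        out = estimate_speeds(fixes, gap_s=300)
        assert list(out["segment_id"]) == [0, 0, 1, 1]
        assert np.isnan(out["dist_m"].iloc[2])  # no distance across the gap

    def test_constant_velocity_recovered_within_1_percent(self):
        v = 1.5  # m/s due north
        step = v * 60.0 / M_PER_DEG_LAT
        track = [(29.7 + k * step, -95.4) for k in range(20)]
        out = estimate_speeds(make_fixes(track, cadence_s=60.0))
        assert np.allclose(out["speed_mps"], v, rtol=0.01)


class TestClassifyStates:
    @pytest.mark.parametrize("speed, state", [
        (0.1, "stationary"), (0.19, "stationary"),
        (0.2, "ambiguous"), (0.5, "ambiguous"), (0.99, "ambiguous"),
        (1.0, "transition"), (1.5, "transition"), (60.0, "transition"),
    ])
    def test_speed_bands(self, speed, state):
        assert classify_speed([speed])[0] == state

    def test_transition_modes(self):
        fixes = make_fixes([(29.7 + k * 0.0008, -95.4) for k in range(6)], cadence_s=60)
        out = estimate_speeds(fixes)  # ~1.48 m/s: walking band
        segs = classify_states(out)
        assert len(segs) == 1 and segs[0].state == "transition"
        assert segs[0].mode == "walking"

    def test_fast_and_slow_runs_merge_separately(self):
        slow = [(29.7, -95.4)] * 5
        fast = [(29.7 + 0.006 * k, -95.4) for k in range(1, 5)]  # ~11 m/s
        out = estimate_speeds(make_fixes(slow + fast, cadence_s=60))
        segs = classify_states(out)
        states = [s.state for s in segs]
        assert states == ["stationary", "transition"]
        assert segs[1].mode == "automobile"

    def test_implausibly_fast_is_unknown_mode(self):
        fixes = make_fixes([(29.7 + 0.03 * k, -95.4) for k in range(4)], cadence_s=60)
        segs = classify_states(estimate_speeds(fixes))  # ~55 m/s
        assert segs[0].mode == "unknown"


class TestAdaptiveKMeans:
    def test_single_tight_disc_one_cluster(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([
            29.7 + rng.normal(0, 30 / M_PER_DEG_LAT, 200),
            -95.4 + rng.normal(0, 30 / M_PER_DEG_LAT, 200),
        ])
        km = adaptive_kmeans(pts, seed=0)
        assert km.n_clusters_ == 1
        assert km.max_distance_m_ <= 500

    def test_two_separated_groups_recovered(self):
        rng = np.random.default_rng(1)
        g1 = np.column_stack([29.7 + rng.normal(0, 50 / M_PER_DEG_LAT, 100),
                              -95.4 + rng.normal(0, 50 / M_PER_DEG_LAT, 100)])
        g2 = g1 + np.array([5000.0 / M_PER_DEG_LAT, 0.0])  # 5 km north
        km = adaptive_kmeans(np.vstack([g1, g2]), seed=0)
        assert km.n_clusters_ == 2
        # centres land on the per-group centroids (the two-means optimum)
        for group in (g1, g2):
            centroid = group.mean(axis=0)
            d = min(vincenty_distance(centroid[0], centroid[1], c[0], c[1])
                    for c in km.cluster_centers_)
            assert d < 50.0

    def test_coverage_on_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = rng.integers(1, 60)
            pts = np.column_stack([
                40.0 + rng.normal(0, 0.02, n), -100.0 + rng.normal(0, 0.02, n)])
            km = adaptive_kmeans(pts, seed=3)
            assert km.max_distance_m_ <= 500.0 + 1e-6

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        pts = np.column_stack([29.7 + rng.normal(0, 0.01, 80),
                               -95.4 + rng.normal(0, 0.01, 80)])
        a = adaptive_kmeans(pts, seed=9)
        b = adaptive_kmeans(pts, seed=9)
        assert np.array_equal(a.labels_, b.labels_)
        assert np.allclose(a.cluster_centers_, b.cluster_centers_)

    def test_empty_input_gives_empty_model(self):
        km = AdaptiveKMeans().fit(np.zeros((0, 2)))
        assert km.n_clusters_ == 0 and len(km.cluster_centers_) == 0


class TestEntropyAndVariance:
    def test_uniform_dwell_is_maximal(self):
        assert normalized_entropy([1.0, 1.0, 1.0], 3) == pytest.approx(1.0)

    def test_hand_computed_three_place_day(self):
        assert normalized_entropy([0.5, 0.25, 0.25], 3) == pytest.approx(0.9464, abs=1e-3)

    def test_single_place_zero_and_single_cluster_undefined(self):
        assert normalized_entropy([5.0], 4) == 0.0
        assert np.isnan(normalized_entropy([5.0], 1))

    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=8))
    def test_bounded_in_unit_interval(self, dwell):
        h = normalized_entropy(dwell, max(len(dwell), 2))
        assert 0.0 <= h <= 1.0 + 1e-12

    def test_base_invariance(self):
        # ratio of logarithms: any log base gives the same value
        p = np.array([0.6, 0.3, 0.1])
        n = 5
        expected = -(p * np.log2(p)).sum() / np.log2(n)
        assert normalized_entropy(p, n) == pytest.approx(expected, rel=1e-12)

    def test_location_variance_matches_definition(self):
        rng = np.random.default_rng(5)
        lats = 29.7 + rng.normal(0, 0.01, 100)
        lons = -95.4 + rng.normal(0, 0.02, 100)
        expected = np.log(np.var(lats) + np.var(lons))
        assert location_variance(lats, lons) == pytest.approx(expected, rel=1e-12)

    def test_single_point_hits_floor(self):
        assert location_variance([29.7] * 5, [-95.4] * 5) == VARIANCE_FLOOR


def _bundle_for(gps=None, steps=None):
    return SensorBundle("s", "teen", TZ,
                        gps=gps if gps is not None else None or _empty_gps(),
                        steps=steps if steps is not None else _empty_steps())


def _empty_gps():
    return pd.DataFrame({"timestamp": pd.Series(dtype="datetime64[ns, UTC]"),
                         "latitude": pd.Series(dtype=float),
                         "longitude": pd.Series(dtype=float)})


def _empty_steps():
    return pd.DataFrame({"timestamp": pd.Series(dtype="datetime64[ns, UTC]"),
                         "count": pd.Series(dtype=int)})


class TestDailyMobility:
    def test_steps_partitioned_by_window_and_sum_preserved(self):
        # 18:00 UTC = noon CST (day); 06:00 UTC = midnight CST (night of prev day)
        ts = pd.to_datetime(["2017-01-02 18:00:00", "2017-01-03 06:00:00"]).tz_localize("UTC")
        steps = pd.DataFrame({"timestamp": ts, "count": [120, 30]})
        table = extract_mobility(_bundle_for(steps=steps))
        assert table["steps_day"].sum() + table["steps_night"].sum() == 150
        row = table[table["date"] == date(2017, 1, 2)].iloc[0]
        assert row["steps_day"] == 120 and row["steps_night"] == 30

    def test_day_without_fixes_keeps_steps_and_drops_gps_features(self):
        ts = pd.to_datetime(["2017-01-02 18:00:00"]).tz_localize("UTC")
        steps = pd.DataFrame({"timestamp": ts, "count": [500]})
        table = extract_mobility(_bundle_for(steps=steps))
        row = table.iloc[0]
        assert row["steps_day"] == 500
        assert np.isnan(row["location_variance"]) and np.isnan(row["normalized_entropy"])

    def test_cohort_step_totals_conserved(self, small_cohort):
        _, bundles, _ = small_cohort
        b = bundles[0]
        table = extract_mobility(b)
        assert table["steps_day"].sum() + table["steps_night"].sum() == b.steps["count"].sum()

    def _two_place_day(self, scale=1.0):
        base = np.array([29.7, -95.4])
        a = [base + [k * 1e-5, 0] for k in range(30)]       # jitter at place A
        b = [base + [0.02 * scale + k * 1e-5, 0] for k in range(30)]  # ~2.2*scale km away
        return make_fixes(np.vstack([a, b]), cadence_s=100)

    def test_dilation_increases_variance_and_distance(self):
        small = extract_mobility(_bundle_for(gps=self._two_place_day(1.0)))
        big = extract_mobility(_bundle_for(gps=self._two_place_day(2.0)))
        assert big["location_variance"].iloc[0] > small["location_variance"].iloc[0]
        assert big["total_distance_km"].iloc[0] > small["total_distance_km"].iloc[0]

    def test_total_distance_bounds_endpoint_distance(self):
        fixes = self._two_place_day(1.0)
        table = extract_mobility(_bundle_for(gps=fixes))
        straight = vincenty_distance(fixes["latitude"].iloc[0], fixes["longitude"].iloc[0],
                                     fixes["latitude"].iloc[-1], fixes["longitude"].iloc[-1])
        assert table["total_distance_km"].iloc[0] * 1000 >= straight - 1e-6

    def test_single_point_day_features(self):
        fixes = make_fixes([(29.7, -95.4)] * 20, cadence_s=120)
        table = extract_mobility(_bundle_for(gps=fixes))
        row = table.iloc[0]
        assert row["n_places_visited"] == 1
        assert row["location_variance"] == VARIANCE_FLOOR
        # a single study-wide cluster makes the entropy normaliser ln(1): undefined
        assert np.isnan(row["normalized_entropy"])
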