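"""Biweekly aggregation and Pearson correlation with significance stars."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from digiphen.stats import (
    aggregate_biweekly,
    correlation_matrix,
    pearson_with_stars,
    stars_for,
)


def _daily(subject, start, values, feature="x"):
    days = pd.date_range(start, periods=len(values), freq="D").date
    return pd.DataFrame({"subject_id": subject, "date": days, feature: values})


def _visits(subject, visit_date, phq9=10, ham_d=17, ham_a=15):
    return pd.DataFrame({"subject_id": [subject], "visit_date": [visit_date],
                         "phq9": [phq9], "ham_d": [ham_d], "ham_a": [ham_a]})


class TestAggregateBiweekly:
    def test_constant_feature_aggregates_to_itself(self):
        daily = _daily("s1", date(2017, 1, 1), [5.0] * 14)
        obs = aggregate_biweekly(daily, _visits("s1", date(2017, 1, 14)))
        assert obs["x"].iloc[0] == 5.0

    def test_missing_days_ignored_and_counted(self):
        values = [2.0] * 7 + [np.nan] * 7
        daily = _daily("s1", date(2017, 1, 1), values)
        obs, counts = aggregate_biweekly(daily, _visits("s1", date(2017, 1, 14)),
                                         return_counts=True)
        assert obs["x"].iloc[0] == 2.0
        assert counts["x"].iloc[0] == 7

    def test_window_is_half_open_behind_visit(self):
        # day exactly 14 before the visit is excluded, the visit day included
        days = [date(2017, 1, 1), date(2017, 1, 2), date(2017, 1, 15)]
        daily = pd.DataFrame({"subject_id": "s1", "date": days, "x": [100.0, 1.0, 3.0]})
        obs = aggregate_biweekly(daily, _visits("s1", date(2017, 1, 15)))
        assert obs["x"].iloc[0] == 2.0  # mean of Jan 2 and Jan 15 only

    def test_matches_groupby_mean_oracle(self):
        rng = np.random.default_rng(0)
        days = pd.date_range("2017-01-01", periods=28, freq="D").date
        daily = pd.DataFrame({"subject_id": "s1", "date": list(days),
                              "x": rng.normal(size=28), "y": rng.normal(size=28)})
        visits = pd.DataFrame({"subject_id": ["s1", "s1"],
                               "visit_date": [date(2017, 1, 14), date(2017, 1, 28)],
                               "phq9": [9, 12], "ham_d": [15, 19], "ham_a": [13, 16]})
        obs = aggregate_biweekly(daily, visits)
        for i, vd in enumerate(visits["visit_date"]):
            window = daily[(pd.to_datetime(daily["date"]).dt.date > vd - pd.Timedelta(days=14).to_pytimedelta())
                           & (pd.to_datetime(daily["date"]).dt.date <= vd)]
            assert obs["x"].iloc[i] == pytest.approx(window["x"].mean())
            assert obs["y"].iloc[i] == pytest.approx(window["y"].mean())


class TestPearson:
    def test_perfect_linearity(self):
        res = pearson_with_stars([1, 2, 3, 4, 5], [3, 5, 7, 9, 11])
        assert res.r == pytest.approx(1.0)
        assert res.stars == "***"

    def test_hand_computed_value(self):
        res = pearson_with_stars([1, 2, 3], [6, 4, 5])
        assert res.r == pytest.approx(-0.5, abs=1e-12)

    def test_zero_variance_reported_missing(self):
        res = pearson_with_stars([1, 1, 1, 1], [2, 3, 4, 5])
        assert np.isnan(res.r) and res.reason == "zero variance"

    def test_too_few_pairs(self):
        res = pearson_with_stars([1, 2], [3, 4])
        assert np.isnan(res.r) and "pairs" in res.reason

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        r0 = pearson_with_stars(x, y).r
        r1 = pearson_with_stars(3.0 * x + 7.0, y).r
        r2 = pearson_with_stars(x, 0.1 * y - 2.0).r
        assert r0 == pytest.approx(r1) == pytest.approx(r2)

    def test_null_star_rate_near_alpha(self):
        """Independent vectors earn ** (p<.05) at about the nominal rate."""
        rng = np.random.default_rng(2)
        hits = 0
        trials = 400
        for _ in range(trials):
            res = pearson_with_stars(rng.normal(size=30), rng.normal(size=30))
            hits += res.p < 0.05
        rate = hits / trials
        assert 0.02 <= rate <= 0.09  # 0.05 +/- ~3.7 binomial SE

    @pytest.mark.parametrize("p, stars", [
        (0.005, "***"), (0.01, "**"), (0.03, "**"), (0.05, "*"), (0.09, "*"), (0.2, ""),
    ])
    def test_star_thresholds(self, p, stars):
        assert stars_for(p) == stars


class TestCorrelationMatrix:
    def _obs(self, n=40, seed=3):
        rng = np.random.default_rng(seed)
        sev = rng.uniform(0, 27, n)
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "visit_date": date(2017, 2, 1),
            "f_neg": -2.0 * sev + rng.normal(0, 5, n),
            "f_null": rng.normal(size=n),
            "phq9": sev + rng.normal(0, 1, n),
            "ham_d": 1.7 * sev + rng.normal(0, 2, n),
            "ham_a": 1.5 * sev + rng.normal(0, 2, n),
        })

    def test_one_feature_three_scores_three_rows(self):
        out = correlation_matrix(self._obs(), features=["f_neg"])
        assert len(out) == 3
        assert set(out["score"]) == {"phq9", "ham_d", "ham_a"}

    def test_planted_signs_recovered(self):
        out = correlation_matrix(self._obs())
        neg = out[(out.feature == "f_neg") & (out.score == "phq9")].iloc[0]
        assert neg.r < 0 and neg.stars in ("**", "***")
        null = out[(out.feature == "f_null") & (out.score == "phq9")].iloc[0]
        assert abs(null.r) < 0.45

    def test_row_order_invariance(self):
        obs = self._obs()
        shuffled = obs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = correlation_matrix(obs).drop(columns=["n"])
        b = correlation_matrix(shuffled).drop(columns=["n"])
        pd.testing.assert_frame_equal(a, b)

    def test_bh_adjustment_optional(self):
        out = correlation_matrix(self._obs(), adjust="bh")
        assert "q_bh" in out.columns
        ok = out["q_bh"].notna()
        assert (out.loc[ok, "q_bh"] >= out.loc[ok, "p"] - 1e-12).all()
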