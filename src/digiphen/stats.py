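"""Biweekly aggregation and Pearson correlation with clinical scores.

Daily features are averaged over the 14 days ending at each clinic
visit — the half-open window (visit_date - 14 d, visit_date] — and the
resulting subject-visit observations are pooled across subjects into a
single Pearson correlation per (feature, score) pair.  Significance is
annotated with the conventional star scheme * p<.1, ** p<.05,
*** p<.01 (two-sided t test on n-2 df), with no multiple-testing
correction by default; pass ``adjust="bh"`` for Benjamini-Hochberg
q-values when screening many features.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd
from scipy import stats as sps

SCORES = ["phq9", "ham_d", "ham_a"]

STAR_THRESHOLDS = ((0.01, "***"), (0.05, "**"), (0.10, "*"))


def stars_for(p: float) -> str:
    for cut, label in STAR_THRESHOLDS:
        if p < cut:
            return label
    return ""


@dataclass
class CorrelationResult:
    """One pooled Pearson correlation between a feature and a score."""

    feature: str
    score: str
    r: float
    p: float
    n: int
    stars: str
    reason: str = ""  # set when r is undefined (e.g. zero variance)


def aggregate_biweekly(daily: pd.DataFrame, assessments: pd.DataFrame,
                       window_days: int = 14,
                       return_counts: bool = False):
    """Mean of each daily feature over the 14 days before each visit.

    ``daily`` needs ``subject_id``, ``date`` and feature columns;
    ``assessments`` needs ``subject_id``, ``visit_date`` and the
    psychometric scores.  A feature with no non-missing day in a window
    stays missing.  With ``return_counts`` the per-feature day counts
    used in each window are returned alongside, for QC.
    """
    feature_cols = [c for c in daily.columns if c not in ("subject_id", "date")]
    daily = daily.assign(date=pd.to_datetime(daily["date"]).dt.date)
    rows, counts = [], []
    for _, visit in assessments.iterrows():
        vdate = pd.to_datetime(visit["visit_date"]).date()
        lo = vdate - timedelta(days=window_days)
        sub = daily[(daily["subject_id"] == visit["subject_id"])
                    & (daily["date"] > lo) & (daily["date"] <= vdate)]
        feats = sub[feature_cols].apply(pd.to_numeric, errors="coerce")
        row = {"subject_id": visit["subject_id"], "visit_date": vdate}
        row.update(feats.mean(skipna=True).to_dict())
        for score in SCORES:
            if score in visit.index:
                row[score] = visit[score]
        rows.append(row)
        cnt = {"subject_id": visit["subject_id"], "visit_date": vdate}
        cnt.update(feats.notna().sum().to_dict())
        counts.append(cnt)
    obs = pd.DataFrame(rows)
    if return_counts:
        return obs, pd.DataFrame(counts)
    return obs


def pearson_with_stars(x, y, feature: str = "x", score: str = "y") -> CorrelationResult:
    """Pooled Pearson r with a two-sided p-value and significance stars.

    Pairs with a missing value in either vector are dropped.  Undefined
    correlations (fewer than 3 complete pairs, or zero variance) are
    reported as missing with a reason rather than raised.
    """
    x = pd.to_numeric(pd.Series(list(x)), errors="coerce")
    y = pd.to_numeric(pd.Series(list(y)), errors="coerce")
    ok = x.notna() & y.notna()
    x, y = x[ok].to_numpy(float), y[ok].to_numpy(float)
    n = len(x)
    if n < 3:
        return CorrelationResult(feature, score, np.nan, np.nan, n, "",
                                 reason=f"only {n} complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(feature, score, np.nan, np.nan, n, "",
                                 reason="zero variance")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(feature, score, float(r), float(p), n, stars_for(float(p)))


def correlation_matrix(observations: pd.DataFrame,
                       features: list[str] | None = None,
                       scores: list[str] | None = None,
                       adjust: str | None = None) -> pd.DataFrame:
    """All (feature, score) Pearson correlations, long format.

    Rows are ordered feature-major, mirroring a correlation heat-map
    read row by row.  ``adjust="bh"`` appends Benjamini-Hochberg
    q-values (the stars still reflect raw p-values, matching the
    uncorrected convention of the correlation figures this mirrors).
    """
    if scores is None:
        scores = [s for s in SCORES if s in observations.columns]
    if features is None:
        features = [c for c in observations.columns
                    if c not in scores + ["subject_id", "visit_date"]]
    results = []
    for feat in features:
        for score in scores:
            res = pearson_with_stars(observations[feat], observations[score],
                                     feature=feat, score=score)
            results.append(res.__dict__)
    out = pd.DataFrame(results)
    if adjust == "bh" and len(out):
        from statsmodels.stats.multitest import multipletests

        mask = out["p"].notna()
        q = np.full(len(out), np.nan)
        if mask.any():
            q[mask.to_numpy()] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
        out["q_bh"] = q
    return out
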