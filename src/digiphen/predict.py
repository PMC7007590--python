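"""PHQ-9 prediction from feature subsets.

Biweekly observations are split 4:1 into train and test sets; a linear
regressor and a polynomial-kernel support vector regressor are fitted
on nine preset feature subsets (self-reports, parent reports, sensor
groups and their combinations).  Performance is reported as the test
RMSE in PHQ-9 points, the variance score (test-set coefficient of
determination, 1 - SS_res/SS_tot, which can be negative when the model
is worse than predicting the mean) and an accuracy percentage
100 x (27 - RMSE)/27 that rescales the error by the PHQ-9 range.

Standardisation and median imputation are fitted on the training set
only, inside an sklearn Pipeline, so no test information leaks into the
preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

PHQ9_SCALE = 27.0

MODELS = ("linear", "svr_poly")

#: feature-group -> daily feature columns (after biweekly aggregation)
FEATURE_GROUPS: dict[str, list[str]] = {
    "teens_inputs": ["teen_mood", "teen_anxiety"],
    "parents_inputs": ["parent_mood", "parent_anxiety"],
    "steps": ["steps_day", "steps_night"],
    "gps": [
        "total_distance_km", "transition_time_auto_h", "transition_time_walk_h",
        "transition_time_unknown_h", "location_variance", "n_places_visited",
        "normalized_entropy", "home_stay",
    ],
    "sms": ["n_sms_top10", "sms_length_total", "sms_length_mean"],
    "call": [
        "n_unique_call_partners", "n_calls_top10",
        "call_duration_total_s", "call_duration_mean_s",
    ],
    "light": ["dark_hours_night"],
    "screen": ["screen_hours_night", "screen_hours_day"],
}


def _cols(*groups: str) -> list[str]:
    out: list[str] = []
    for g in groups:
        out.extend(FEATURE_GROUPS[g])
    return out


#: the nine preset subsets, in presentation order
FEATURE_SUBSETS: dict[str, list[str]] = {
    "all_features": _cols("teens_inputs", "parents_inputs", "steps", "gps",
                          "sms", "call", "light", "screen"),
    "teens_inputs": _cols("teens_inputs"),
    "parents_inputs": _cols("parents_inputs"),
    "teens_parents_inputs": _cols("teens_inputs", "parents_inputs"),
    "all_sensors": _cols("steps", "gps", "sms", "call", "light", "screen"),
    "steps_gps_sms_call": _cols("steps", "gps", "sms", "call"),
    "teens_inputs_steps_gps_sms_call": _cols("teens_inputs", "steps", "gps",
                                             "sms", "call"),
    "parents_inputs_steps_gps_sms_call": _cols("parents_inputs", "steps", "gps",
                                               "sms", "call"),
    "teens_parents_inputs_steps_gps_sms_call": _cols("teens_inputs", "parents_inputs",
                                                     "steps", "gps", "sms", "call"),
}


class Phq9Regressor(RegressorMixin, BaseEstimator):
    """Predict PHQ-9 from aggregated features.

    A thin sklearn estimator wrapping median imputation, train-set
    standardisation and either ordinary least squares (``model=
    "linear"``) or a polynomial-kernel support vector regressor
    (``model="svr_poly"``, degree 3 and default regularisation — the
    conventional defaults, since nothing beyond "polynomial kernel" is
    prescribed).

    Attributes
    ----------
    pipeline_ : sklearn Pipeline, after :meth:`fit`.
    n_features_in_ : int
    """

    def __init__(self, model: str = "linear", degree: int = 3,
                 C: float = 1.0, epsilon: float = 0.1):
        self.model = model
        self.degree = degree
        self.C = C
        self.epsilon = epsilon

    def _make_regressor(self):
        if self.model == "linear":
            return LinearRegression()
        if self.model == "svr_poly":
            return SVR(kernel="poly", degree=self.degree, C=self.C, epsilon=self.epsilon)
        raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per target value")
        if len(X) == 0:
            raise ValueError("empty training set")
        self.pipeline_ = Pipeline([
            ("impute", SimpleImputer(strategy="median", keep_empty_features=True)),
            ("scale", StandardScaler()),
            ("reg", self._make_regressor()),
        ])
        self.pipeline_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return self.pipeline_.predict(np.asarray(X, dtype=float))


@dataclass
class PredictionReport:
    """Test-set performance of one (subset, model) combination."""

    subset: str
    model: str
    rmse: float
    variance_score: float  # test-set R^2; NaN when the test target is constant
    accuracy_percent: float
    accuracy_numerator: float  # the "x/27" numerator, 27 - rmse
    n_train: int
    n_test: int
    seed: int | None = None


def split_train_test(observations: pd.DataFrame, test_fraction: float = 0.2,
                     seed: int | None = 0, by_subject: bool = False):
    """Random 4:1 split of observation rows (deterministic under seed).

    ``by_subject=True`` keeps all visits of a subject on the same side
    — row-level splitting lets the model see every subject during
    training, which flatters the error estimate.
    """
    if by_subject:
        subjects = np.array(sorted(observations["subject_id"].unique()))
        tr, te = train_test_split(subjects, test_size=test_fraction, random_state=seed)
        return (observations[observations["subject_id"].isin(tr)].copy(),
                observations[observations["subject_id"].isin(te)].copy())
    return train_test_split(observations, test_size=test_fraction, random_state=seed)


def accuracy_from_rmse(rmse: float, scale: float = PHQ9_SCALE) -> float:
    """Rescale an RMSE to a percentage of the score range.

    100 x (scale - rmse)/scale: 0 error is 100%, an error of the whole
    range is 0%.  Strictly decreasing in the RMSE.
    """
    if not 0 <= rmse <= scale:
        raise ValueError(f"rmse must be within [0, {scale}]")
    return 100.0 * (scale - rmse) / scale


def fit_and_evaluate(train: pd.DataFrame, test: pd.DataFrame, subset: str,
                     model: str, target: str = "phq9",
                     seed: int | None = None) -> PredictionReport:
    """Fit one model on one feature subset and score it on the test set."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    cols = FEATURE_SUBSETS[subset] if isinstance(subset, str) else list(subset)
    name = subset if isinstance(subset, str) else "+".join(subset)
    missing = [c for c in cols if c not in train.columns]
    if missing:
        raise KeyError(f"features not in observations: {missing}")
    reg = Phq9Regressor(model=model).fit(train[cols], train[target])
    pred = np.clip(reg.predict(test[cols]), 0.0, PHQ9_SCALE)
    y = test[target].to_numpy(float)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    variance = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    return PredictionReport(
        subset=name, model=model, rmse=rmse, variance_score=variance,
        accuracy_percent=accuracy_from_rmse(min(rmse, PHQ9_SCALE)),
        accuracy_numerator=round(PHQ9_SCALE - min(rmse, PHQ9_SCALE), 2),
        n_train=len(train), n_test=len(test), seed=seed,
    )


def run_table1(observations: pd.DataFrame, seed: int | None = 0,
               by_subject: bool = False) -> pd.DataFrame:
    """Evaluate every preset subset with both regressors on one split.

    Returns 18 rows (9 subsets x 2 models), long format.
    """
    train, test = split_train_test(observations, seed=seed, by_subject=by_subject)
    rows = [
        asdict(fit_and_evaluate(train, test, subset, model, seed=seed))
        for subset in FEATURE_SUBSETS
        for model in MODELS
    ]
    return pd.DataFrame(rows)


def table1_wide(reports: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long report table into subset rows x model metric columns."""
    wide = reports.pivot(index="subset", columns="model",
                         values=["rmse", "variance_score"])
    wide.columns = [f"{model}_{metric}" for metric, model in wide.columns]
    return wide.loc[[s for s in FEATURE_SUBSETS if s in wide.index]].reset_index()
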