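"""GPS and step-count mobility features.

From a subject's raw GPS trace we estimate instantaneous speeds,
classify each fix as stationary (< 0.2 m/s) or in transition
(>= 1 m/s), cluster the stationary fixes into frequently visited places
(smallest number of clusters such that every fix lies within 500 m of
its centre), and then summarise each day:

* ``steps_day`` / ``steps_night`` — step counts in the 7 AM-11 PM and
  11 PM-7 AM windows;
* ``total_distance_km`` — geodesic mileage accumulated along the trace;
* ``transition_time_{auto,walk,unknown}_h`` — time in motion by mode
  (automobile 7-45 m/s, walking 1-2 m/s, otherwise unknown);
* ``location_variance`` — ln(var(latitude) + var(longitude)) of the
  day's stationary fixes, variances in degrees squared;
* ``n_places_visited`` — study-wide clusters touched that day;
* ``normalized_entropy`` — Shannon entropy of the day's dwell-time
  fractions across places, divided by ln of the study-wide cluster
  count, so 1 means time spread uniformly and 0 a single place;
* ``home_stay`` — fraction of the day's stationary dwell spent in the
  home cluster (the cluster holding the largest share of night-time
  stationary dwell over the whole study; the source data never define
  "home", so this night-dwell rule is this package's convention).

Speeds in the dead zone [0.2, 1) m/s are labelled ``ambiguous`` and
take part in neither clustering nor transition time.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .geo import WGS84_A, consecutive_distances, vincenty_distance
from .types import DayWindow, assign_windows

STATIONARY_MAX_SPEED = 0.2  # m/s
TRANSITION_MIN_SPEED = 1.0  # m/s
AUTOMOBILE_BAND = (7.0, 45.0)  # m/s
WALKING_BAND = (1.0, 2.0)  # m/s
DEFAULT_RADIUS_M = 500.0
DEFAULT_GAP_S = 300.0  # gaps longer than this split the trace
VARIANCE_FLOOR = np.log(1e-12)

GPS_FEATURES = [
    "total_distance_km",
    "transition_time_auto_h",
    "transition_time_walk_h",
    "transition_time_unknown_h",
    "location_variance",
    "n_places_visited",
    "normalized_entropy",
    "home_stay",
]
MOBILITY_FEATURES = ["steps_day", "steps_night"] + GPS_FEATURES


def estimate_speeds(fixes: pd.DataFrame, gap_s: float = DEFAULT_GAP_S) -> pd.DataFrame:
    """Per-fix speed (m/s) and gap-segment id for a sorted GPS trace.

    Speed at fix k is the geodesic distance from fix k-1 divided by the
    elapsed time; the first fix of each segment inherits the second's
    speed.  Gaps longer than ``gap_s`` split the trace into independent
    segments — no speed (and no travelled distance) is carried across a
    gap.  Single-fix segments have undefined (NaN) speed.

    Returns a copy of ``fixes`` with ``speed_mps``, ``segment_id`` and
    ``dist_m`` (distance from the previous fix, NaN across gaps).
    """
    out = fixes.copy().reset_index(drop=True)
    n = len(out)
    if n == 0:
        out["speed_mps"] = pd.Series(dtype=float)
        out["segment_id"] = pd.Series(dtype=int)
        out["dist_m"] = pd.Series(dtype=float)
        return out
    t = out["timestamp"].astype("int64").to_numpy() / 1e9
    dt = np.diff(t)
    if np.any(dt < 0):
        raise ValueError("fixes must be sorted by timestamp")
    dist = consecutive_distances(out["latitude"].to_numpy(), out["longitude"].to_numpy())
    new_seg = np.concatenate([[True], dt > gap_s])
    segment_id = np.cumsum(new_seg) - 1
    speed = np.full(n, np.nan)
    within = np.concatenate([[False], ~new_seg[1:]])
    idx = np.flatnonzero(within)
    with np.errstate(divide="ignore", invalid="ignore"):
        speed[idx] = dist[idx - 1] / dt[idx - 1]
    # first fix of each multi-fix segment inherits its successor's speed
    first = np.flatnonzero(new_seg)
    has_next = np.concatenate([first[1:] > first[:-1] + 1, [n > first[-1] + 1]])
    inherit = first[has_next]
    speed[inherit] = speed[inherit + 1]
    dist_m = np.full(n, np.nan)
    dist_m[idx] = dist[idx - 1]
    out["speed_mps"] = speed
    out["segment_id"] = segment_id
    out["dist_m"] = dist_m
    return out


def classify_speed(speed: np.ndarray | pd.Series) -> np.ndarray:
    """Map speeds to per-fix states: stationary / transition / ambiguous."""
    speed = np.asarray(speed, dtype=float)
    state = np.full(speed.shape, "ambiguous", dtype=object)
    state[speed < STATIONARY_MAX_SPEED] = "stationary"
    state[speed >= TRANSITION_MIN_SPEED] = "transition"
    return state


@dataclass
class MotionSegment:
    """A maximal run of fixes sharing one motion state."""

    start: pd.Timestamp
    end: pd.Timestamp
    state: str  # stationary | transition | ambiguous
    mode: str | None  # automobile | walking | unknown (transitions only)
    mean_speed: float
    n_fixes: int

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


def transition_mode(mean_speed: float) -> str:
    if AUTOMOBILE_BAND[0] <= mean_speed <= AUTOMOBILE_BAND[1]:
        return "automobile"
    if WALKING_BAND[0] <= mean_speed <= WALKING_BAND[1]:
        return "walking"
    return "unknown"


def classify_states(fixes_with_speed: pd.DataFrame) -> list[MotionSegment]:
    """Merge contiguous equal-state fixes into :class:`MotionSegment` runs.

    Runs never span a gap split.  Transition segments get a transport
    mode from their mean speed (automobile 7-45 m/s, walking 1-2 m/s,
    otherwise unknown — which also catches > 45 m/s).
    """
    df = fixes_with_speed
    if len(df) == 0:
        return []
    state = classify_speed(df["speed_mps"].to_numpy())
    seg = df["segment_id"].to_numpy()
    change = np.concatenate([[True], (state[1:] != state[:-1]) | (seg[1:] != seg[:-1])])
    starts = np.flatnonzero(change)
    ends = np.concatenate([starts[1:] - 1, [len(df) - 1]])
    ts = df["timestamp"].reset_index(drop=True)
    speeds = df["speed_mps"].to_numpy()
    segments = []
    for i0, i1 in zip(starts, ends):
        run = speeds[i0:i1 + 1]
        finite = run[~np.isnan(run)]
        mean_speed = float(finite.mean()) if finite.size else float("nan")
        st = state[i0]
        segments.append(
            MotionSegment(
                start=ts.iloc[i0],
                end=ts.iloc[i1],
                state=st,
                mode=transition_mode(mean_speed) if st == "transition" else None,
                mean_speed=mean_speed,
                n_fixes=int(i1 - i0 + 1),
            )
        )
    return segments


class AdaptiveKMeans(ClusterMixin, BaseEstimator):
    """K-means with the number of places grown until a radius is covered.

    Starting from one cluster, K is increased until every point lies
    within ``radius_m`` (geodesic) of its assigned centre — the smallest
    K under this incremental procedure.  Lloyd iterations run on a local
    equirectangular projection (plain lat/lon means are distorted at
    high latitude); the coverage check uses true WGS84 geodesic
    distances, so the radius guarantee is honest.

    Attributes (after :meth:`fit`)
    ------------------------------
    cluster_centers_ : ndarray of shape (K, 2) — latitude, longitude.
    labels_ : ndarray of shape (n,) — assignment of each input point.
    n_clusters_ : int
    max_distance_m_ : float — largest point-to-centre geodesic distance.
    """

    def __init__(self, radius_m: float = DEFAULT_RADIUS_M, n_init: int = 4,
                 random_state: int | None = 0):
        self.radius_m = radius_m
        self.n_init = n_init
        self.random_state = random_state

    def _project(self, latlon: np.ndarray) -> np.ndarray:
        lat0, lon0 = self._origin_
        x = np.radians(latlon[:, 1] - lon0) * np.cos(np.radians(lat0)) * WGS84_A
        y = np.radians(latlon[:, 0] - lat0) * WGS84_A
        return np.column_stack([x, y])

    def _unproject(self, xy: np.ndarray) -> np.ndarray:
        lat0, lon0 = self._origin_
        lat = lat0 + np.degrees(xy[:, 1] / WGS84_A)
        lon = lon0 + np.degrees(xy[:, 0] / (WGS84_A * np.cos(np.radians(lat0))))
        return np.column_stack([lat, lon])

    def fit(self, X, y=None):
        """Cluster an (n, 2) array of latitude/longitude degrees."""
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            self.cluster_centers_ = np.zeros((0, 2))
            self.labels_ = np.zeros(0, dtype=int)
            self.n_clusters_ = 0
            self.max_distance_m_ = 0.0
            return self
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2) latitude/longitude degrees")
        self._origin_ = (float(X[:, 0].mean()), float(X[:, 1].mean()))
        xy = self._project(X)
        n_unique = len(np.unique(xy, axis=0))
        for k in range(1, n_unique + 1):
            km = KMeans(n_clusters=k, n_init=self.n_init, random_state=self.random_state)
            labels = km.fit_predict(xy)
            centers = self._unproject(km.cluster_centers_)
            dists = vincenty_distance(X[:, 0], X[:, 1],
                                      centers[labels, 0], centers[labels, 1])
            max_d = float(np.max(dists))
            if max_d <= self.radius_m or k == n_unique:
                self.cluster_centers_ = centers
                self.labels_ = labels
                self.n_clusters_ = k
                self.max_distance_m_ = max_d
                return self
        return self  # pragma: no cover

    def predict(self, X):
        """Assign points to the geodesically nearest fitted centre."""
        X = np.asarray(X, dtype=float)
        if self.n_clusters_ == 0:
            return np.zeros(len(X), dtype=int)
        d = np.stack(
            [
                np.asarray(vincenty_distance(X[:, 0], X[:, 1], c[0], c[1]))
                for c in self.cluster_centers_
            ],
            axis=1,
        )
        return np.argmin(d, axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def adaptive_kmeans(latlon, radius_m: float = DEFAULT_RADIUS_M, seed: int | None = 0) -> AdaptiveKMeans:
    """Functional wrapper: fit :class:`AdaptiveKMeans` on lat/lon degrees."""
    return AdaptiveKMeans(radius_m=radius_m, random_state=seed).fit(np.asarray(latlon, dtype=float))


def location_variance(lats, lons) -> float:
    """ln(var(longitude) + var(latitude)) in degrees squared.

    Population variances; floored at ln(1e-12) when the day's fixes are
    (numerically) a single point.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.size == 0:
        return float("nan")
    total = float(np.var(lats) + np.var(lons))
    if total <= 1e-12:
        return VARIANCE_FLOOR
    return float(np.log(total))


def normalized_entropy(dwell, n_total_clusters: int) -> float:
    """Shannon entropy of dwell fractions over ln(study-wide cluster count).

    ``dwell`` holds the day's dwell times (any nonnegative weights) over
    the places visited that day; they are renormalised internally.
    Returns 0.0 when all dwell is in one place, and NaN (undefined) when
    the study has a single cluster overall.
    """
    if n_total_clusters <= 1:
        return float("nan")
    p = np.asarray(dwell, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        return float("nan")
    if p.size == 1:
        return 0.0
    p = p / p.sum()
    return float(-(p * np.log(p)).sum() / np.log(n_total_clusters))


def _dwell_weights(fixes: pd.DataFrame) -> np.ndarray:
    """Dwell seconds attributed to each fix: the gap to the next fix
    within the same gap-segment (the last fix of a segment gets 0)."""
    t = fixes["timestamp"].astype("int64").to_numpy() / 1e9
    seg = fixes["segment_id"].to_numpy()
    dwell = np.zeros(len(fixes))
    if len(fixes) > 1:
        dt = np.diff(t)
        same = seg[1:] == seg[:-1]
        dwell[:-1] = np.where(same, dt, 0.0)
    return dwell


def _prepare_fixes(gps: pd.DataFrame, tz: str, gap_s: float) -> pd.DataFrame:
    fixes = estimate_speeds(gps, gap_s=gap_s)
    fixes["state"] = classify_speed(fixes["speed_mps"])
    win = assign_windows(fixes["timestamp"], tz)
    fixes["obs_date"] = win["obs_date"].to_numpy()
    fixes["window"] = win["window"].to_numpy()
    fixes["dwell_s"] = _dwell_weights(fixes)
    return fixes


def fit_place_clusters(gps: pd.DataFrame, tz: str, radius_m: float = DEFAULT_RADIUS_M,
                       seed: int | None = 0, gap_s: float = DEFAULT_GAP_S) -> AdaptiveKMeans:
    """Cluster a subject's study-wide stationary fixes into places."""
    fixes = _prepare_fixes(gps, tz, gap_s)
    stationary = fixes[fixes["state"] == "stationary"]
    return adaptive_kmeans(stationary[["latitude", "longitude"]].to_numpy(),
                           radius_m=radius_m, seed=seed)


def _home_cluster(stationary: pd.DataFrame) -> int | None:
    """Cluster with the largest share of study-wide night-time dwell."""
    night = stationary[stationary["window"] == "night"]
    pool = night if night["dwell_s"].sum() > 0 else stationary
    if len(pool) == 0:
        return None
    shares = pool.groupby("place")["dwell_s"].sum()
    if shares.max() <= 0:
        shares = pool.groupby("place").size()
    return int(shares.idxmax())


def extract_mobility(bundle, clusters: AdaptiveKMeans | None = None, *,
                     radius_m: float = DEFAULT_RADIUS_M, seed: int | None = 0,
                     gap_s: float = DEFAULT_GAP_S) -> pd.DataFrame:
    """Daily mobility features for one subject bundle.

    Returns one row per observed day (``subject_id``, ``date`` and the
    :data:`MOBILITY_FEATURES` columns).  Days with step events but no
    usable GPS still appear, with the GPS features missing.
    """
    tz = bundle.timezone
    gps, steps = bundle.gps, bundle.steps

    # --- steps, partitioned by the day/night windows
    step_rows = pd.DataFrame(columns=["steps_day", "steps_night"])
    if len(steps):
        win = assign_windows(steps["timestamp"], tz)
        grouped = (
            steps.assign(obs_date=win["obs_date"].to_numpy(), window=win["window"].to_numpy())
            .groupby(["obs_date", "window"], sort=True)["count"].sum()
            .unstack(fill_value=0)
        )
        step_rows = grouped.rename(columns={"day": "steps_day", "night": "steps_night"})
        for col in ("steps_day", "steps_night"):
            if col not in step_rows:
                step_rows[col] = 0
        step_rows = step_rows[["steps_day", "steps_night"]]

    gps_rows = pd.DataFrame(columns=GPS_FEATURES)
    if len(gps) > 0:
        fixes = _prepare_fixes(gps, tz, gap_s)
        stationary_mask = fixes["state"] == "stationary"
        if clusters is None:
            clusters = adaptive_kmeans(
                fixes.loc[stationary_mask, ["latitude", "longitude"]].to_numpy(),
                radius_m=radius_m, seed=seed)
        stationary = fixes[stationary_mask].copy()
        if len(stationary):
            stationary["place"] = clusters.predict(
                stationary[["latitude", "longitude"]].to_numpy())
        else:
            stationary["place"] = pd.Series(dtype=int)
        n_total = clusters.n_clusters_
        home = _home_cluster(stationary) if len(stationary) else None

        # distance: consecutive same-segment hops, attributed to the
        # later fix's observation date
        dist = (
            fixes.dropna(subset=["dist_m"]).groupby("obs_date")["dist_m"].sum() / 1000.0
        ).rename("total_distance_km")

        # transition time by mode, attributed to the segment's start date
        trans_segs = [s for s in classify_states(fixes) if s.state == "transition"]
        if trans_segs:
            starts = pd.Series([s.start for s in trans_segs])
            d0 = assign_windows(starts, tz)["obs_date"]
            seg_df = pd.DataFrame({
                "obs_date": d0.to_numpy(),
                "mode": [s.mode for s in trans_segs],
                "hours": [s.duration_s / 3600.0 for s in trans_segs],
            })
            trans = seg_df.pivot_table(index="obs_date", columns="mode", values="hours",
                                       aggfunc="sum", fill_value=0.0)
        else:
            trans = pd.DataFrame()
        for mode in ("automobile", "walking", "unknown"):
            if mode not in trans:
                trans[mode] = 0.0
        trans = trans.rename(columns={"automobile": "transition_time_auto_h",
                                      "walking": "transition_time_walk_h",
                                      "unknown": "transition_time_unknown_h"})

        per_day = {}
        for day, grp in stationary.groupby("obs_date"):
            dwell = grp.groupby("place")["dwell_s"].sum()
            dwell = dwell[dwell > 0]
            per_day[day] = {
                "location_variance": location_variance(grp["latitude"], grp["longitude"]),
                "n_places_visited": int(grp["place"].nunique()),
                "normalized_entropy": normalized_entropy(dwell.to_numpy(), n_total),
                "home_stay": (
                    float(dwell.get(home, 0.0) / dwell.sum())
                    if home is not None and dwell.sum() > 0 else float("nan")
                ),
            }
        station_df = pd.DataFrame.from_dict(per_day, orient="index")
        gps_rows = pd.concat([dist, trans, station_df], axis=1)
        missing_trans = [c for c in GPS_FEATURES if c not in gps_rows.columns]
        for c in missing_trans:
            gps_rows[c] = np.nan
        gps_rows = gps_rows[GPS_FEATURES]
        # a day with transitions but no stationary fixes keeps NaN place stats
        gps_rows[["transition_time_auto_h", "transition_time_walk_h",
                  "transition_time_unknown_h"]] = gps_rows[
            ["transition_time_auto_h", "transition_time_walk_h",
             "transition_time_unknown_h"]].fillna(0.0)
        gps_rows["total_distance_km"] = gps_rows["total_distance_km"].fillna(0.0)

    out = step_rows.join(gps_rows, how="outer") if len(step_rows) or len(gps_rows) else (
        pd.DataFrame(columns=["steps_day", "steps_night"] + GPS_FEATURES))
    for col in ("steps_day", "steps_night"):
        if col in out:
            out[col] = pd.to_numeric(out[col], errors="coerce").fillna(0).astype(int)
    out.index.name = "date"
    out = out.reset_index()
    if len(out):
        out["date"] = pd.to_datetime(out["date"]).dt.date
    out.insert(0, "subject_id", bundle.subject_id)
    return out


def daily_mobility(gps: pd.DataFrame, steps: pd.DataFrame,
                   clusters: AdaptiveKMeans | None, window: DayWindow, tz: str,
                   **kwargs) -> pd.Series:
    """Mobility features for one :class:`DayWindow`.

    Convenience wrapper over :func:`extract_mobility` — the cluster
    model must span the whole study (places are defined study-wide),
    while the returned row covers only ``window.date``.
    """
    from .types import SensorBundle

    bundle = SensorBundle(subject_id="_", role="teen", timezone=tz,
                          gps=gps.reset_index(drop=True), steps=steps.reset_index(drop=True))
    table = extract_mobility(bundle, clusters=clusters, **kwargs)
    row = table[table["date"] == window.date]
    if len(row) == 0:
        empty = pd.Series({c: (0 if c.startswith("steps") else np.nan)
                           for c in MOBILITY_FEATURES})
        empty["date"] = window.date
        return empty
    return row.iloc[0].drop("subject_id")
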