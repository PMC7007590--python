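"""Daily-living-context features: ambient light and screen usage.

Ambient light is logged every ~2 minutes; averaging it per clock hour
and counting night hours darker than a lux threshold tau_I gives a
cheap proxy for sleep duration.  Screen state is sampled every ~30 s;
an hour counts as a usage hour when its screen-on fraction exceeds
tau_S (default 10%).  Hours with no samples are treated as missing, not
as dark/off — sensor dropout must not masquerade as sleep.

Both thresholds use strict inequalities: dark means mean lux < tau_I,
usage means on-fraction > tau_S.
"""

from __future__ import annotations

from zoneinfo import ZoneInfo

import pandas as pd
from pydantic import BaseModel, Field

from .types import DAY_START_HOUR, NIGHT_START_HOUR, assign_windows

CONTEXT_FEATURES = ["dark_hours_night", "screen_hours_night", "screen_hours_day"]

NIGHT_HOURS = 8
DAY_HOURS = 16


class ContextConfig(BaseModel):
    """Thresholds for the living-context features.

    tau_I_lux: darkness bound on the hourly mean ambient light.  The
    source protocol calls this empirical; 10 lux is a conventional
    indoor-darkness bound and is configurable here.
    tau_S: screen-on fraction above which an hour counts as usage.
    """

    tau_I_lux: float = Field(default=10.0, gt=0)
    tau_S: float = Field(default=0.10, gt=0, lt=1)


def _hourly(samples: pd.DataFrame, tz: str, value_col: str) -> pd.DataFrame:
    """Per (obs_date, window, clock-hour) mean of a sampled stream."""
    if len(samples) == 0:
        return pd.DataFrame(columns=["obs_date", "window", "hour", "mean"])
    local = pd.DatetimeIndex(samples["timestamp"]).tz_convert(ZoneInfo(tz))
    win = assign_windows(samples["timestamp"], tz)
    df = pd.DataFrame({
        "obs_date": win["obs_date"].to_numpy(),
        "window": win["window"].to_numpy(),
        "hour": local.hour,
        "value": pd.to_numeric(samples[value_col]).to_numpy(),
    })
    out = df.groupby(["obs_date", "window", "hour"], sort=True)["value"].mean()
    return out.rename("mean").reset_index()


def hourly_light_means(samples: pd.DataFrame, tz: str) -> pd.DataFrame:
    """Mean lux per local clock hour; uncovered hours are simply absent."""
    return _hourly(samples, tz, "lux")


def dark_hours(hour_means: pd.DataFrame, tau_I: float) -> pd.DataFrame:
    """Count night hours with mean lux strictly below ``tau_I`` per day.

    Returns per-day rows with ``dark_hours_night`` and
    ``n_missing_hours`` (night hours without any light sample, excluded
    from the count rather than assumed dark).
    """
    night = hour_means[hour_means["window"] == "night"]
    if len(night) == 0:
        return pd.DataFrame(columns=["obs_date", "dark_hours_night", "n_missing_hours"])
    grp = night.groupby("obs_date")["mean"]
    out = pd.DataFrame({
        "dark_hours_night": grp.apply(lambda s: int((s < tau_I).sum())),
        "n_missing_hours": NIGHT_HOURS - grp.size(),
    })
    return out.reset_index()


def screen_hours(samples: pd.DataFrame, tz: str, tau_S: float) -> pd.DataFrame:
    """Hours per day/night window with screen-on fraction strictly above tau_S."""
    if len(samples) == 0:
        return pd.DataFrame(columns=["obs_date", "screen_hours_day", "screen_hours_night"])
    frac = _hourly(samples.assign(on_num=samples["on"].astype(float)), tz, "on_num")
    counts = (
        frac.assign(used=frac["mean"] > tau_S)
        .groupby(["obs_date", "window"])["used"].sum()
        .unstack(fill_value=0)
    )
    counts = counts.rename(columns={"day": "screen_hours_day", "night": "screen_hours_night"})
    for col in ("screen_hours_day", "screen_hours_night"):
        if col not in counts:
            counts[col] = 0
        counts[col] = counts[col].astype(int)
    return counts.reset_index()


def extract_context(bundle, config: ContextConfig | None = None) -> pd.DataFrame:
    """Daily context features for one subject bundle."""
    config = config or ContextConfig()
    tz = bundle.timezone
    light = dark_hours(hourly_light_means(bundle.light, tz), config.tau_I_lux)
    screen = screen_hours(bundle.screen, tz, config.tau_S)
    out = pd.merge(
        light.drop(columns=["n_missing_hours"], errors="ignore"),
        screen, on="obs_date", how="outer",
    )
    out = out.rename(columns={"obs_date": "date"})
    for col in CONTEXT_FEATURES:
        if col not in out:
            out[col] = pd.NA
    out = out[["date"] + CONTEXT_FEATURES].sort_values("date").reset_index(drop=True)
    if len(out):
        out["date"] = pd.to_datetime(out["date"]).dt.date
    out.insert(0, "subject_id", bundle.subject_id)
    return out
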