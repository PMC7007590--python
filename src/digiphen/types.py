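"""Core record types, identifier hashing and day/night windowing.

Raw smartphone streams (GPS fixes, step events, call/SMS logs, ambient
light, screen state) are held as pandas DataFrames inside a
:class:`SensorBundle`, one bundle per subject.  The schemas, value
ranges and the local-time day/night convention defined here are shared
by every feature extractor.

Day/night convention: the *day* window of calendar date D is
[D 07:00, D 23:00) and the *night* window is [D 23:00, D+1 07:00), both
in the subject's local civil time.  The night that starts at 23:00 on
date D belongs to D.  The two half-open windows tile the clock, so
every sample is attributed to exactly one (date, window) pair.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass, field, replace
from datetime import date as _date, time, timedelta
from typing import Iterator
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

CALL_DIRECTIONS = ("incoming", "outgoing", "missed")
SMS_DIRECTIONS = ("incoming", "outgoing")
REPORTERS = ("teen", "parent_self", "parent_about_teen")

DAY_START_HOUR = 7
NIGHT_START_HOUR = 23

#: stream name -> (column, pandas dtype kind) pairs, timestamp column first
STREAM_SCHEMAS: dict[str, list[str]] = {
    "gps": ["timestamp", "latitude", "longitude"],
    "steps": ["timestamp", "count"],
    "calls": ["timestamp", "contact_hash", "direction", "duration_s"],
    "sms": ["timestamp", "contact_hash", "direction", "length"],
    "light": ["timestamp", "lux"],
    "screen": ["timestamp", "on"],
}

#: non-stream tables carried in a bundle (keyed on dates, not timestamps)
TABLE_SCHEMAS: dict[str, list[str]] = {
    "reports": ["date", "reporter", "mood", "anxiety"],
    "assessments": ["visit_date", "phq9", "ham_d", "ham_a"],
}


class ValidationError(ValueError):
    """A record or stream violates its schema or value ranges."""


_PHONE_JUNK = re.compile(r"[\s\-\.\(\)\+]")


def canonicalize_identifier(raw_id: str) -> str:
    """Normalise a contact identifier before hashing.

    Phone numbers keep digits only (so ``555-123-4567`` and
    ``5551234567`` are the same contact); anything else (e-mail
    addresses, account names) is lower-cased and stripped.
    """
    if not isinstance(raw_id, str) or not raw_id.strip():
        raise ValidationError("identifier must be a non-empty string")
    stripped = _PHONE_JUNK.sub("", raw_id)
    if stripped.isdigit():
        return stripped
    return raw_id.strip().lower()


def hash_identifier(raw_id: str) -> str:
    """One-way MD5 digest of a canonicalized contact identifier.

    Hashing happens at ingest so that raw phone numbers and addresses
    never reach disk; all downstream tables carry only the 32-character
    hex digest.
    """
    canon = canonicalize_identifier(raw_id)
    return hashlib.md5(canon.encode("utf-8")).hexdigest()


def compliance_rate(n_submitted: int, n_expected: int) -> float:
    """Percentage of enrolled days with a submitted daily report.

    Reported to one decimal, e.g. 498 of 630 days -> 79.0.
    """
    if n_expected <= 0:
        raise ValidationError("n_expected must be positive")
    if not 0 <= n_submitted <= n_expected:
        raise ValidationError("need 0 <= n_submitted <= n_expected")
    return round(100.0 * n_submitted / n_expected, 1)


@dataclass(frozen=True)
class DayWindow:
    """The day/night windows of one local calendar date."""

    date: _date

    @property
    def day_start(self) -> time:
        return time(DAY_START_HOUR)

    @property
    def night_start(self) -> time:
        return time(NIGHT_START_HOUR)

    def span(self, tz: str) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Full [07:00 of date, 07:00 of date+1) span as aware timestamps."""
        z = ZoneInfo(tz)
        start = pd.Timestamp.combine(pd.Timestamp(self.date), self.day_start).tz_localize(z)
        return start, start + pd.Timedelta(days=1)


def assign_windows(timestamps: pd.Series | pd.DatetimeIndex, tz: str) -> pd.DataFrame:
    """Attribute each UTC timestamp to its (obs_date, window) pair.

    Vectorized over the input; returns a DataFrame with columns
    ``obs_date`` (python date) and ``window`` ("day" | "night")
    following the convention in the module docstring.
    """
    ts = pd.DatetimeIndex(timestamps)
    if ts.tz is None:
        raise ValidationError("timestamps must be timezone-aware (UTC)")
    local = ts.tz_convert(ZoneInfo(tz)).tz_localize(None)
    hours = local.hour
    is_day = (hours >= DAY_START_HOUR) & (hours < NIGHT_START_HOUR)
    dates = local.normalize()
    # early-morning night hours belong to the previous calendar date
    obs_date = dates.where(hours >= DAY_START_HOUR, dates - pd.Timedelta(days=1))
    return pd.DataFrame(
        {
            "obs_date": obs_date,  # naive midnight datetimes, cheap to group on
            "window": np.where(is_day, "day", "night"),
        },
        index=timestamps.index if isinstance(timestamps, pd.Series) else None,
    )


def _empty_stream(name: str) -> pd.DataFrame:
    cols = STREAM_SCHEMAS.get(name) or TABLE_SCHEMAS[name]
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
    if name in STREAM_SCHEMAS:
        df["timestamp"] = pd.Series(dtype="datetime64[ns, UTC]")
    return df


@dataclass
class SensorBundle:
    """All raw streams and report series for one subject.

    Streams are pandas DataFrames following :data:`STREAM_SCHEMAS`, with
    UTC timestamps sorted ascending; ``timezone`` is the IANA zone in
    which the subject's civil days are cut.
    """

    subject_id: str
    role: str  # "teen" | "parent"
    timezone: str
    gps: pd.DataFrame = field(default_factory=lambda: _empty_stream("gps"))
    steps: pd.DataFrame = field(default_factory=lambda: _empty_stream("steps"))
    calls: pd.DataFrame = field(default_factory=lambda: _empty_stream("calls"))
    sms: pd.DataFrame = field(default_factory=lambda: _empty_stream("sms"))
    light: pd.DataFrame = field(default_factory=lambda: _empty_stream("light"))
    screen: pd.DataFrame = field(default_factory=lambda: _empty_stream("screen"))
    reports: pd.DataFrame = field(default_factory=lambda: _empty_stream("reports"))
    assessments: pd.DataFrame = field(default_factory=lambda: _empty_stream("assessments"))

    def streams(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for name in STREAM_SCHEMAS:
            yield name, getattr(self, name)

    def tables(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for name in TABLE_SCHEMAS:
            yield name, getattr(self, name)

    def validate(self) -> "SensorBundle":
        """Check schemas, ranges and ordering; returns self."""
        if self.role not in ("teen", "parent"):
            raise ValidationError(f"role must be teen|parent, got {self.role!r}")
        ZoneInfo(self.timezone)  # raises on unknown zone
        for name, df in self.streams():
            errors = validate_stream(name, df)
            if errors:
                raise ValidationError(
                    f"{self.subject_id}/{name}: " + "; ".join(errors[:10])
                )
        for name, df in self.tables():
            errors = validate_stream(name, df)
            if errors:
                raise ValidationError(
                    f"{self.subject_id}/{name}: " + "; ".join(errors[:10])
                )
        return self

    def sorted(self) -> "SensorBundle":
        """Return a copy with every stream sorted by timestamp."""
        kwargs = {}
        for name, df in self.streams():
            kwargs[name] = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
        return replace(self, **kwargs)

    def equals(self, other: "SensorBundle") -> bool:
        if (self.subject_id, self.role, self.timezone) != (
            other.subject_id, other.role, other.timezone,
        ):
            return False
        for name in list(STREAM_SCHEMAS) + list(TABLE_SCHEMAS):
            a = getattr(self, name).reset_index(drop=True)
            b = getattr(other, name).reset_index(drop=True)
            if len(a) != len(b):
                return False
            if len(a) == 0:
                continue
            try:
                pd.testing.assert_frame_equal(a[sorted(a.columns)], b[sorted(b.columns)],
                                              check_dtype=False, check_exact=False)
            except AssertionError:
                return False
        return True


_HEX = re.compile(r"^[0-9a-f]{32}$")


def validate_stream(name: str, df: pd.DataFrame) -> list[str]:
    """Schema and range checks for one stream; returns row-level error strings.

    Each message names the offending 0-based row so that file readers
    can map it back to a line number.
    """
    schema = STREAM_SCHEMAS.get(name) or TABLE_SCHEMAS.get(name)
    if schema is None:
        return [f"unknown stream {name!r}"]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        return [f"missing columns {missing}"]
    extra = [c for c in df.columns if c not in schema]
    if extra:
        return [f"unknown columns {extra}"]
    errors: list[str] = []

    def bad(mask: pd.Series, message: str) -> None:
        for row in np.flatnonzero(np.asarray(mask))[:20]:
            errors.append(f"row {row}: {message}")

    if len(df) == 0:
        return errors
    if name in STREAM_SCHEMAS:
        ts = df["timestamp"]
        if not pd.api.types.is_datetime64_any_dtype(ts) or getattr(ts.dt, "tz", None) is None:
            errors.append("timestamp column must be timezone-aware datetimes")
            return errors
    if name == "gps":
        lat = pd.to_numeric(df["latitude"], errors="coerce")
        lon = pd.to_numeric(df["longitude"], errors="coerce")
        bad(~((lat >= -90) & (lat <= 90)), "latitude outside [-90, 90]")
        bad(~((lon >= -180) & (lon <= 180)), "longitude outside [-180, 180]")
    elif name == "steps":
        count = pd.to_numeric(df["count"], errors="coerce")
        bad(~(count >= 1), "step count must be >= 1")
    elif name == "calls":
        bad(~df["direction"].isin(CALL_DIRECTIONS), "direction not incoming|outgoing|missed")
        dur = pd.to_numeric(df["duration_s"], errors="coerce")
        bad(~(dur >= 0), "duration_s must be >= 0")
        bad((df["direction"] == "missed") & (dur != 0), "missed call with nonzero duration")
        bad(~df["contact_hash"].astype(str).str.match(_HEX), "contact_hash not a 32-char hex digest")
    elif name == "sms":
        bad(~df["direction"].isin(SMS_DIRECTIONS), "direction not incoming|outgoing")
        length = pd.to_numeric(df["length"], errors="coerce")
        bad(~(length >= 0), "length must be >= 0")
        bad(~df["contact_hash"].astype(str).str.match(_HEX), "contact_hash not a 32-char hex digest")
    elif name == "light":
        lux = pd.to_numeric(df["lux"], errors="coerce")
        bad(~(lux >= 0), "lux must be >= 0")
    elif name == "screen":
        on = df["on"]
        bad(~on.isin([True, False]), "on must be boolean")
    elif name == "reports":
        bad(~df["reporter"].isin(REPORTERS), "unknown reporter")
        for col in ("mood", "anxiety"):
            v = pd.to_numeric(df[col], errors="coerce")
            bad(~((v >= 0) & (v <= 100)), f"{col} outside [0, 100]")
    elif name == "assessments":
        for col, hi in (("phq9", 27), ("ham_d", 52), ("ham_a", 56)):
            v = pd.to_numeric(df[col], errors="coerce")
            bad(~((v >= 0) & (v <= hi)), f"{col} outside [0, {hi}]")
    return errors


def ensure_sorted(name: str, df: pd.DataFrame, subject_id: str = "?") -> pd.DataFrame:
    """Sort a stream by timestamp, warning if it was out of order."""
    col = "timestamp" if name in STREAM_SCHEMAS else TABLE_SCHEMAS[name][0]
    if len(df) and not df[col].is_monotonic_increasing:
        warnings.warn(
            f"{subject_id}/{name}: rows out of timestamp order; re-sorting",
            stacklevel=2,
        )
        df = df.sort_values(col, kind="stable").reset_index(drop=True)
    return df


def enrollment_days(bundle: SensorBundle) -> int:
    """Number of enrolled days spanned by the bundle's streams/reports."""
    dates: list[_date] = []
    for _, df in bundle.streams():
        if len(df):
            local = df["timestamp"].dt.tz_convert(ZoneInfo(bundle.timezone))
            dates.append(local.min().date())
            dates.append(local.max().date())
    if len(bundle.reports):
        d = pd.to_datetime(bundle.reports["date"])
        dates.append(d.min().date())
        dates.append(d.max().date())
    if not dates:
        return 0
    return (max(dates) - min(dates)).days + 1


def date_range_days(start: _date, n_days: int) -> list[_date]:
    return [start + timedelta(days=i) for i in range(n_days)]
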