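"""Call- and SMS-based social interaction features.

Daily statistics are restricted to each subject's top-10 most frequent
contacts over the whole study, ranked separately for calls and for SMS
("most frequent" = number of records; ties broken by total
duration/length, then by hash, so the selection is deterministic).
``n_unique_call_partners`` is the one exception: it counts distinct
partners over *all* of the day's calls.  Missed calls count as calls
but contribute nothing to duration statistics.  All outputs carry only
MD5 contact hashes, never raw identifiers.
"""

from __future__ import annotations

import pandas as pd

from .types import assign_windows

SOCIAL_FEATURES = [
    "n_unique_call_partners",
    "n_calls_top10",
    "call_duration_total_s",
    "call_duration_mean_s",
    "n_calls_all",
    "n_sms_top10",
    "sms_length_total",
    "sms_length_mean",
    "n_sms_all",
]


def top_frequent_contacts(records: pd.DataFrame, k: int = 10,
                          weight_col: str | None = None) -> list[str]:
    """The k most frequent contact hashes in a call or SMS log.

    Frequency is the record count per contact; ties are broken by the
    summed ``weight_col`` (call duration or SMS length) and then by the
    hash itself, lexicographically.  Order-invariant in the input rows.
    """
    if len(records) == 0:
        return []
    if weight_col is None:
        weight_col = "duration_s" if "duration_s" in records.columns else "length"
    stats = (
        records.groupby("contact_hash")
        .agg(n=("contact_hash", "size"), w=(weight_col, "sum"))
        .reset_index()
        .sort_values(by=["n", "w", "contact_hash"],
                     ascending=[False, False, True], kind="stable")
    )
    return stats["contact_hash"].head(k).tolist()


def daily_social(calls: pd.DataFrame, sms: pd.DataFrame,
                 top10_calls: list[str], top10_sms: list[str]) -> dict:
    """Social features for one day's records (already date-filtered)."""
    out = dict.fromkeys(SOCIAL_FEATURES, 0.0)
    out["n_unique_call_partners"] = int(calls["contact_hash"].nunique()) if len(calls) else 0
    out["n_calls_all"] = int(len(calls))
    out["n_sms_all"] = int(len(sms))
    if len(calls):
        top = calls[calls["contact_hash"].isin(top10_calls)]
        out["n_calls_top10"] = int(len(top))
        answered = top[top["direction"] != "missed"]
        out["call_duration_total_s"] = float(answered["duration_s"].sum())
        out["call_duration_mean_s"] = (
            float(answered["duration_s"].mean()) if len(answered) else 0.0
        )
    if len(sms):
        top = sms[sms["contact_hash"].isin(top10_sms)]
        out["n_sms_top10"] = int(len(top))
        out["sms_length_total"] = float(top["length"].sum())
        out["sms_length_mean"] = float(top["length"].mean()) if len(top) else 0.0
    return out


def extract_social(bundle, k: int = 10) -> pd.DataFrame:
    """Daily social-interaction features for one subject bundle.

    One row per day on which any call or SMS was logged; days without
    records simply do not appear (they are zero-filled downstream when
    merged against the enrollment calendar).
    """
    tz = bundle.timezone
    calls, sms = bundle.calls, bundle.sms
    top10_calls = top_frequent_contacts(calls, k=k) if len(calls) else []
    top10_sms = top_frequent_contacts(sms, k=k) if len(sms) else []

    def with_date(df):
        if len(df) == 0:
            return df.assign(obs_date=pd.Series(dtype=object))
        return df.assign(obs_date=assign_windows(df["timestamp"], tz)["obs_date"].to_numpy())

    calls, sms = with_date(calls), with_date(sms)
    dates = sorted(set(calls["obs_date"]) | set(sms["obs_date"]))
    rows = []
    for day in dates:
        rec = daily_social(
            calls[calls["obs_date"] == day], sms[sms["obs_date"] == day],
            top10_calls, top10_sms,
        )
        rec["date"] = day
        rows.append(rec)
    out = pd.DataFrame(rows, columns=["date"] + SOCIAL_FEATURES)
    if len(out):
        out["date"] = pd.to_datetime(out["date"]).dt.date
    out.insert(0, "subject_id", bundle.subject_id)
    return out
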