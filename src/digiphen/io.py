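"""Reading and writing sensor bundles.

One file per stream (CSV with a mandatory header, or JSON lines), plus a
YAML manifest naming the subject, role, IANA timezone and the stream
file paths.  Timestamps are ISO-8601 with offset on disk and UTC in
memory.  Reading validates every row and reports offending line numbers;
out-of-order rows are re-sorted with a warning rather than rejected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    STREAM_SCHEMAS,
    TABLE_SCHEMAS,
    SensorBundle,
    ValidationError,
    ensure_sorted,
    validate_stream,
)

MANIFEST_NAME = "manifest.yaml"


@dataclass
class RowError:
    """One unreadable or out-of-range row in a stream file."""

    path: str
    line: int  # 1-based line number in the file (header = line 1 for CSV)
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}:{self.line}: {self.message}"


class BundleReadError(ValidationError):
    def __init__(self, errors: list[RowError]):
        self.errors = errors
        preview = "\n".join(str(e) for e in errors[:20])
        more = "" if len(errors) <= 20 else f"\n... and {len(errors) - 20} more"
        super().__init__(f"{len(errors)} invalid rows:\n{preview}{more}")


def _date_col(name: str) -> str:
    return "timestamp" if name in STREAM_SCHEMAS else TABLE_SCHEMAS[name][0]


def _serialize(name: str, df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    col = _date_col(name)
    if name in STREAM_SCHEMAS:
        out[col] = pd.DatetimeIndex(out[col]).tz_convert("UTC").strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    else:
        out[col] = pd.to_datetime(out[col]).astype("datetime64[ns]").astype(str).str[:10]
    if name == "screen" and len(out):
        out["on"] = out["on"].astype(bool)
    return out


def _parse(name: str, df: pd.DataFrame, path: str, offset: int) -> tuple[pd.DataFrame, list[RowError]]:
    """Coerce raw string/object columns to the schema, collecting row errors."""
    errors: list[RowError] = []
    schema = STREAM_SCHEMAS.get(name) or TABLE_SCHEMAS[name]
    missing = [c for c in schema if c not in df.columns]
    extra = [c for c in df.columns if c not in schema]
    if missing or extra:
        errors.append(RowError(path, 1, f"columns {sorted(df.columns)} != expected {schema}"))
        return df, errors
    col = _date_col(name)
    if name in STREAM_SCHEMAS:
        ts = pd.to_datetime(df[col], errors="coerce", utc=True, format="ISO8601")
    else:
        ts = pd.to_datetime(df[col], errors="coerce", format="%Y-%m-%d")
    for row in np.flatnonzero(ts.isna().to_numpy()):
        errors.append(RowError(path, row + offset, f"unparsable {col}: {df[col].iloc[row]!r}"))
    df = df.assign(**{col: ts})
    if name == "screen" and len(df):
        on = df["on"]
        if on.dtype == object:
            on = on.map({"True": True, "true": True, True: True,
                         "False": False, "false": False, False: False})
        df = df.assign(on=on)
    for msg in validate_stream(name, df):
        if msg.startswith("row "):
            row, rest = msg[4:].split(":", 1)
            errors.append(RowError(path, int(row) + offset, rest.strip()))
        else:
            errors.append(RowError(path, 1, msg))
    if name not in STREAM_SCHEMAS:
        df = df.assign(**{col: df[col].dt.date})
    return df, errors


def write_bundle(bundle: SensorBundle, directory: str | Path, fmt: str = "csv") -> Path:
    """Write one file per stream plus a manifest; returns the manifest path.

    ``fmt`` is ``"csv"`` or ``"jsonl"``.
    """
    if fmt not in ("csv", "jsonl"):
        raise ValueError(f"format must be csv or jsonl, got {fmt!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "subject_id": bundle.subject_id,
        "role": bundle.role,
        "timezone": bundle.timezone,
        "format": fmt,
        "streams": {},
    }
    for name in list(STREAM_SCHEMAS) + list(TABLE_SCHEMAS):
        df = _serialize(name, getattr(bundle, name))
        fname = f"{name}.{fmt}"
        fpath = directory / fname
        if fmt == "csv":
            df.to_csv(fpath, index=False)
        else:
            with open(fpath, "w") as fh:
                for rec in df.to_dict(orient="records"):
                    fh.write(json.dumps(rec, default=str) + "\n")
        manifest["streams"][name] = fname
    mpath = directory / MANIFEST_NAME
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return mpath


def read_bundle(manifest_path: str | Path, missing_streams: str = "error") -> SensorBundle:
    """Load a bundle from its manifest.

    Parameters
    ----------
    missing_streams : {"error", "warn"}
        With ``"warn"``, a stream file listed in the manifest but absent
        on disk yields an empty stream and a warning instead of an
        error, so a pipeline can proceed with the remaining channels.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    for key in ("subject_id", "role", "timezone", "format", "streams"):
        if key not in manifest:
            raise ValidationError(f"manifest missing key {key!r}")
    fmt = manifest["format"]
    base = manifest_path.parent
    kwargs: dict[str, pd.DataFrame] = {}
    errors: list[RowError] = []
    for name in list(STREAM_SCHEMAS) + list(TABLE_SCHEMAS):
        rel = manifest["streams"].get(name)
        fpath = base / rel if rel else None
        if fpath is None or not fpath.exists():
            if missing_streams == "warn" or rel is None:
                warnings.warn(f"{manifest['subject_id']}: stream file for {name!r} "
                              "missing; continuing with empty stream", stacklevel=2)
                continue
            raise FileNotFoundError(fpath)
        if fmt == "csv":
            raw = pd.read_csv(fpath, dtype=object, keep_default_na=False)
            offset = 2  # line 1 is the header
        else:
            records = []
            with open(fpath) as fh:
                for i, line in enumerate(fh):
                    if line.strip():
                        try:
                            records.append(json.loads(line))
                        except json.JSONDecodeError as exc:
                            errors.append(RowError(str(fpath), i + 1, f"bad JSON: {exc}"))
            cols = STREAM_SCHEMAS.get(name) or TABLE_SCHEMAS[name]
            raw = pd.DataFrame(records, columns=cols) if records else pd.DataFrame(columns=cols)
            offset = 1
        if len(raw) == 0:
            continue
        for col in raw.columns:
            if col not in ("timestamp", "date", "visit_date", "direction",
                           "reporter", "contact_hash", "on"):
                raw[col] = pd.to_numeric(raw[col], errors="coerce")
        parsed, errs = _parse(name, raw, str(fpath), offset)
        errors.extend(errs)
        if not errs:
            parsed = ensure_sorted(name, parsed, manifest["subject_id"])
            kwargs[name] = parsed.reset_index(drop=True)
    if errors:
        raise BundleReadError(errors)
    return SensorBundle(
        subject_id=str(manifest["subject_id"]),
        role=manifest["role"],
        timezone=manifest["timezone"],
        **kwargs,
    ).validate()
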