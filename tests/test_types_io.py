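"""Identifier hashing, compliance arithmetic, day/night windowing and bundle I/O."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from digiphen.io import BundleReadError, read_bundle, write_bundle
from digiphen.types import (
    SensorBundle,
    ValidationError,
    assign_windows,
    compliance_rate,
    hash_identifier,
)


class TestHashIdentifier:
    def test_deterministic_and_md5_shaped(self):
        for raw in ("555-123-4567", "someone@example.org", "  Mixed Case  "):
            digest = hash_identifier(raw)
            assert digest == hash_identifier(raw)
            assert len(digest) == 32 and int(digest, 16) >= 0

    def test_phone_number_formats_collapse(self):
        assert hash_identifier("555-123-4567") == hash_identifier("5551234567")
        assert hash_identifier("+1 (713) 555-0101") == hash_identifier("17135550101")

    def test_email_lowercased(self):
        assert hash_identifier("Jo@Example.org ") == hash_identifier("jo@example.org")

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            hash_identifier("   ")


class TestCompliance:
    @pytest.mark.parametrize(
        "submitted, expected, rate",
        [(498, 630, 79.0), (603, 630, 95.7), (0, 10, 0.0), (10, 10, 100.0)],
    )
    def test_rates(self, submitted, expected, rate):
        assert compliance_rate(submitted, expected) == rate

    def test_zero_expected_rejected(self):
        with pytest.raises(ValidationError):
            compliance_rate(0, 0)


class TestDayWindow:
    @given(st.lists(st.datetimes(min_value=pd.Timestamp("2017-01-01").to_pydatetime(),
                                 max_value=pd.Timestamp("2017-12-30").to_pydatetime()),
                    min_size=1, max_size=50))
    def test_partition_covers_every_sample_once(self, naive_times):
        """night + day windows tile the clock: each sample gets exactly
        one (date, window) pair."""
        ts = pd.Series(pd.DatetimeIndex(naive_times).tz_localize("UTC"))
        win = assign_windows(ts, "America/Chicago")
        assert len(win) == len(ts)
        assert set(win["window"]) <= {"day", "night"}
        assert win["obs_date"].notna().all()

    def test_night_belongs_to_starting_date(self):
        # 23:30 local on Jan 10 and 02:00 local on Jan 11 share the same night
        tz = "America/Chicago"
        late = pd.Series(pd.to_datetime(["2017-01-11 05:30:00"]).tz_localize("UTC"))  # 23:30 CST Jan 10
        early = pd.Series(pd.to_datetime(["2017-01-11 08:00:00"]).tz_localize("UTC"))  # 02:00 CST Jan 11
        noon = pd.Series(pd.to_datetime(["2017-01-11 18:00:00"]).tz_localize("UTC"))  # 12:00 CST Jan 11
        for s, window, day in ((late, "night", 10), (early, "night", 10), (noon, "day", 11)):
            win = assign_windows(s, tz)
            assert win["window"].iloc[0] == window
            assert win["obs_date"].iloc[0] == pd.Timestamp(date(2017, 1, day))


def _tiny_bundle() -> SensorBundle:
    ts = pd.to_datetime(
        ["2017-01-02 13:00:00", "2017-01-02 13:05:00", "2017-01-02 13:10:00"]
    ).tz_localize("UTC")
    gps = pd.DataFrame({"timestamp": ts, "latitude": [29.7, 29.701, 29.702],
                        "longitude": [-95.4, -95.401, -95.402]})
    calls = pd.DataFrame({
        "timestamp": ts[:2],
        "contact_hash": [hash_identifier("5551234567")] * 2,
        "direction": ["incoming", "missed"],
        "duration_s": [60.0, 0.0],
    })
    reports = pd.DataFrame({"date": [date(2017, 1, 2)], "reporter": ["teen"],
                            "mood": [55], "anxiety": [60]})
    assessments = pd.DataFrame({"visit_date": [date(2017, 1, 15)], "phq9": [12],
                                "ham_d": [20], "ham_a": [18]})
    return SensorBundle("s01", "teen", "America/Chicago", gps=gps, calls=calls,
                        reports=reports, assessments=assessments).validate()


class TestBundleRoundTrip:
    @pytest.mark.parametrize("fmt", ["csv", "jsonl"])
    def test_round_trip_identity(self, tmp_path, fmt):
        bundle = _tiny_bundle()
        manifest = write_bundle(bundle, tmp_path / fmt, fmt=fmt)
        back = read_bundle(manifest)
        assert back.equals(bundle)

    def test_formats_agree(self, tmp_path):
        bundle = _tiny_bundle()
        a = read_bundle(write_bundle(bundle, tmp_path / "a", fmt="csv"))
        b = read_bundle(write_bundle(bundle, tmp_path / "b", fmt="jsonl"))
        assert a.equals(b)

    def test_out_of_range_latitude_names_the_row(self, tmp_path):
        bundle = _tiny_bundle()
        manifest = write_bundle(bundle, tmp_path, fmt="csv")
        gps_file = tmp_path / "gps.csv"
        lines = gps_file.read_text().splitlines()
        lines[2] = lines[2].replace("29.701", "91.0")
        gps_file.write_text("\n".join(lines) + "\n")
        with pytest.raises(BundleReadError) as err:
            read_bundle(manifest)
        assert any(e.line == 3 and "latitude" in e.message for e in err.value.errors)

    def test_out_of_order_rows_resorted_with_warning(self, tmp_path):
        bundle = _tiny_bundle()
        shuffled = bundle.gps.iloc[[2, 0, 1]].reset_index(drop=True)
        bundle2 = SensorBundle("s01", "teen", "America/Chicago", gps=shuffled,
                               calls=bundle.calls, reports=bundle.reports,
                               assessments=bundle.assessments)
        manifest = write_bundle(bundle2, tmp_path, fmt="csv")
        with pytest.warns(UserWarning, match="out of timestamp order"):
            back = read_bundle(manifest)
        assert back.gps["timestamp"].is_monotonic_increasing

    def test_unknown_column_rejected(self, tmp_path):
        manifest = write_bundle(_tiny_bundle(), tmp_path, fmt="csv")
        gps_file = tmp_path / "gps.csv"
        content = gps_file.read_text().splitlines()
        content[0] += ",speed"
        gps_file.write_text("\n".join(line + ",1" if i else line + ""
                                      for i, line in enumerate(content)) + "\n")
        with pytest.raises((BundleReadError, ValidationError)):
            read_bundle(manifest)

    def test_missing_stream_file_tolerated_on_request(self, tmp_path):
        manifest = write_bundle(_tiny_bundle(), tmp_path, fmt="csv")
        (tmp_path / "gps.csv").unlink()
        with pytest.warns(UserWarning, match="missing"):
            back = read_bundle(manifest, missing_streams="warn")
        assert len(back.gps) == 0 and len(back.calls) == 2


def test_no_raw_identifiers_in_serialized_output(tmp_path, small_cohort):
    """Privacy: raw contact numbers never appear in any written file."""
    _, bundles, _ = small_cohort
    bundle = bundles[0]
    write_bundle(bundle, tmp_path, fmt="csv")
    raw_fragments = ["+1 (713)", "713) 555"]
    for f in tmp_path.iterdir():
        text = f.read_text()
        for frag in raw_fragments:
            assert frag not in text
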