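"""End-to-end orchestration: simulate -> extract -> merge -> correlate -> predict.

Each stage reads and writes plain CSV, so every stage can also be run
standalone on the previous stage's outputs.  A single master seed fans
out deterministically to per-stage seeds (SeedSequence of
[master, stage-index]), and a run manifest records the configuration
hash and library versions, so identical configurations reproduce
byte-identical correlation and prediction tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from datetime import date as _date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .context import ContextConfig, extract_context
from .io import read_bundle, write_bundle
from .mobility import MOBILITY_FEATURES, extract_mobility
from .predict import run_table1, table1_wide
from .simulate import CohortConfig, simulate_cohort
from .social import SOCIAL_FEATURES, extract_social
from .stats import aggregate_biweekly, correlation_matrix
from .types import SensorBundle, compliance_rate

log = logging.getLogger("digiphen")

REPORT_FEATURES = ["teen_mood", "teen_anxiety", "parent_mood", "parent_anxiety"]

_STAGES = ("simulate", "mobility", "social", "context", "merge", "correlate", "predict")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


class RunConfig(BaseModel):
    """Everything one reproducible run needs."""

    master_seed: int = 0
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    context: ContextConfig = Field(default_factory=ContextConfig)
    correlation_adjust: str | None = None  # None or "bh"
    split_by_subject: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(self.model_dump_json()), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


def extract_reports(bundle: SensorBundle) -> pd.DataFrame:
    """Daily EMA features: teen mood/anxiety and the parent's rating of
    the teen, one row per date with any report."""
    rows: dict = {}
    for _, rec in bundle.reports.iterrows():
        day = rec["date"]
        row = rows.setdefault(day, {})
        if rec["reporter"] == "teen":
            row["teen_mood"] = rec["mood"]
            row["teen_anxiety"] = rec["anxiety"]
        elif rec["reporter"] == "parent_about_teen":
            row["parent_mood"] = rec["mood"]
            row["parent_anxiety"] = rec["anxiety"]
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=REPORT_FEATURES)
    out.index.name = "date"
    out = out.sort_index().reset_index()
    out.insert(0, "subject_id", bundle.subject_id)
    return out


def merge_daily(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Outer-join per-domain daily tables on (subject_id, date)."""
    frames = [f for f in frames if f is not None and len(f)]
    if not frames:
        return pd.DataFrame(columns=["subject_id", "date"])
    out = frames[0]
    for f in frames[1:]:
        out = out.merge(f, on=["subject_id", "date"], how="outer")
    return out.sort_values(["subject_id", "date"]).reset_index(drop=True)


def extract_all(bundles: list[SensorBundle], context_config: ContextConfig | None = None,
                cluster_seed: int = 0) -> dict[str, pd.DataFrame]:
    """Run all per-domain extractors over a list of bundles."""
    mob, soc, ctx, rep, assess = [], [], [], [], []
    for b in bundles:
        t0 = time.perf_counter()
        try:
            mob.append(extract_mobility(b, seed=cluster_seed))
        except Exception:
            log.exception("mobility extraction failed for %s; skipping", b.subject_id)
        soc.append(extract_social(b))
        ctx.append(extract_context(b, context_config))
        rep.append(extract_reports(b))
        a = b.assessments.copy()
        a.insert(0, "subject_id", b.subject_id)
        assess.append(a)
        log.info("extracted %s in %.1fs", b.subject_id, time.perf_counter() - t0)

    def cat(frames):
        frames = [f for f in frames if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    return {
        "mobility": cat(mob),
        "social": cat(soc),
        "context": cat(ctx),
        "reports": cat(rep),
        "assessments": cat(assess),
    }


def compliance_summary(bundles: list[SensorBundle], n_expected_days: int) -> pd.DataFrame:
    """Per-reporter compliance across the cohort, as submitted/expected %."""
    rows = []
    for reporter, label in (("teen", "teen"), ("parent_about_teen", "parent")):
        submitted = sum(
            int((b.reports["reporter"] == reporter).sum()) for b in bundles
        )
        expected = n_expected_days * len(bundles)
        rows.append({
            "reporter": label,
            "n_submitted": submitted,
            "n_expected": expected,
            "compliance_percent": compliance_rate(submitted, expected),
        })
    return pd.DataFrame(rows)


def run_all(config: RunConfig, out_dir: str | Path,
            bundles: list[SensorBundle] | None = None) -> Path:
    """Execute the full pipeline into ``out_dir``; returns that path.

    Artifacts: per-subject bundle directories, per-domain feature CSVs,
    the merged daily table, biweekly observations, the correlation
    table, the prediction grid (long and wide) and a human-readable
    summary, plus a run manifest with the config hash and versions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out_dir / "run.log")
    log.addHandler(fh)
    timings: dict[str, float] = {}
    try:
        cohort_cfg = config.cohort.model_copy(
            update={"seed": stage_seed(config.master_seed, "simulate")})
        t0 = time.perf_counter()
        if bundles is None:
            bundles, truth = simulate_cohort(cohort_cfg)
            bdir = out_dir / "bundles"
            for b in bundles:
                write_bundle(b, bdir / b.subject_id)
            truth.to_csv(out_dir / "ground_truth.csv", index=False)
            pd.DataFrame([cohort_cfg.betas()]).to_csv(
                out_dir / "ground_truth_betas.csv", index=False)
        timings["simulate"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        tables = extract_all(bundles, config.context,
                             cluster_seed=stage_seed(config.master_seed, "mobility"))
        for name in ("mobility", "social", "context", "reports"):
            tables[name].to_csv(out_dir / f"{name}.csv", index=False)
        tables["assessments"].to_csv(out_dir / "assessments.csv", index=False)
        timings["extract"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        daily = merge_daily([tables["mobility"], tables["social"],
                             tables["context"], tables["reports"]])
        daily.to_csv(out_dir / "daily_features.csv", index=False)
        obs = aggregate_biweekly(daily, tables["assessments"])
        obs.to_csv(out_dir / "observations.csv", index=False)
        timings["merge"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        corr = correlation_matrix(obs, adjust=config.correlation_adjust)
        corr.to_csv(out_dir / "correlations.csv", index=False)
        timings["correlate"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        reports = run_table1(obs, seed=stage_seed(config.master_seed, "predict"),
                             by_subject=config.split_by_subject)
        reports.to_csv(out_dir / "predictions.csv", index=False)
        table1_wide(reports).to_csv(out_dir / "predictions_wide.csv", index=False)
        timings["predict"] = time.perf_counter() - t0

        comp = compliance_summary(bundles, config.cohort.weeks * 7)
        comp.to_csv(out_dir / "compliance.csv", index=False)

        _write_summary(out_dir, obs, corr, reports, comp)
        manifest = {
            "config_hash": config.config_hash(),
            "versions": _versions(),
            "n_subjects": len(bundles),
            "n_observations": int(len(obs)),
        }
        with open(out_dir / "run_manifest.yaml", "w") as f:
            yaml.safe_dump(manifest, f, sort_keys=True)
        config.to_yaml(out_dir / "config.yaml")
        for stage, dt in timings.items():
            log.info("stage %s: %.1fs", stage, dt)
    finally:
        log.removeHandler(fh)
        fh.close()
    return out_dir


def _versions() -> dict[str, str]:
    import sklearn
    import scipy

    return {
        "digiphen": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "scipy": scipy.__version__,
    }


def _write_summary(out_dir: Path, obs, corr, reports, comp) -> None:
    lines = ["digiphen pipeline summary", "=" * 30, ""]
    lines.append(f"biweekly observations: {len(obs)}")
    for _, row in comp.iterrows():
        lines.append(
            f"{row['reporter']} compliance: {row['compliance_percent']}% "
            f"({row['n_submitted']}/{row['n_expected']} days)")
    lines.append("")
    lines.append("strongest correlations with PHQ-9:")
    sub = corr[(corr["score"] == "phq9") & corr["r"].notna()]
    for _, row in sub.reindex(sub["r"].abs().sort_values(ascending=False).index).head(8).iterrows():
        lines.append(f"  {row['feature']:<28s} r={row['r']:+.2f} {row['stars']}")
    lines.append("")
    best = reports.loc[reports["rmse"].idxmin()]
    lines.append(
        f"best prediction: {best['subset']} / {best['model']} "
        f"RMSE={best['rmse']:.2f} accuracy={best['accuracy_percent']:.0f}% "
        f"({best['accuracy_numerator']:.2f}/27)")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")


def load_bundles(bundle_dir: str | Path, missing_streams: str = "warn") -> list[SensorBundle]:
    """Read every bundle manifest below a directory."""
    paths = sorted(Path(bundle_dir).glob("*/manifest.yaml"))
    return [read_bundle(p, missing_streams=missing_streams) for p in paths]
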