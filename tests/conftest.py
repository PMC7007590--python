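"""Shared fixtures: small synthetic cohorts and their derived tables."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from digiphen.pipeline import extract_all, merge_daily
from digiphen.simulate import CohortConfig, simulate_cohort
from digiphen.stats import aggregate_biweekly

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """An 8-family cohort with default study conditions (one generation
    per test session; treat as read-only)."""
    config = CohortConfig(n_families=8, seed=123)
    bundles, truth = simulate_cohort(config)
    return config, bundles, truth


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    config, bundles, _ = small_cohort
    return extract_all(bundles)


@pytest.fixture(scope="session")
def small_daily(small_tables) -> pd.DataFrame:
    t = small_tables
    return merge_daily([t["mobility"], t["social"], t["context"], t["reports"]])


@pytest.fixture(scope="session")
def small_observations(small_daily, small_tables) -> pd.DataFrame:
    return aggregate_biweekly(small_daily, small_tables["assessments"])
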