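"""Shared fixtures: small seeded phantom cohorts and feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dlmvoi import PhantomConfig, simulate_cohort_with_clicks
from dlmvoi.evaluation import extract_cohort_table


@pytest.fixture(scope="session")
def small_cohort():
    """12-case default-condition phantom with simulated clicks."""
    cfg = PhantomConfig(n_cases=12, seed=7)
    cases, clicks = simulate_cohort_with_clicks(cfg)
    return cfg, cases, clicks


@pytest.fixture(scope="session")
def small_feature_table(small_cohort) -> pd.DataFrame:
    """18-mm VOI feature table for the 12-case phantom."""
    _, cases, clicks = small_cohort
    return extract_cohort_table(cases, clicks, diameter_mm=18.0)


@pytest.fixture(scope="session")
def signal_table() -> tuple[pd.DataFrame, np.ndarray]:
    """Synthetic tabular data with a few informative and many noise features."""
    rng = np.random.default_rng(42)
    n = 300
    y = (rng.random(n) < 0.4).astype(int)
    cols = {}
    for i in range(3):
        cols[f"signal_{i}"] = y * 1.5 + rng.standard_normal(n)
    for i in range(20):
        cols[f"noise_{i}"] = rng.standard_normal(n)
    return pd.DataFrame(cols), y
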