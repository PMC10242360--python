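"""Shared fixtures: small hand-built cohorts and cached simulator truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import rwcea

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_cohort(followup, death, arm, secondline_end=None, thirdline=None,
                covariate=None):
    """Minimal analysis-ready cohort frame from per-patient vectors."""
    n = len(followup)
    fu = np.asarray(followup, dtype=float)
    sl = np.asarray(secondline_end, dtype=float) if secondline_end is not None \
        else np.minimum(fu, 30.0)
    t3 = np.asarray(thirdline, dtype=float) if thirdline is not None \
        else np.full(n, np.nan)
    x = np.asarray(covariate, dtype=float) if covariate is not None \
        else np.arange(n, dtype=float) % 3
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "arm": arm,
        "x": x,
        "followup_days": fu,
        "death": np.asarray(death, dtype=int),
        "secondline_end_day": sl,
        "thirdline_start_day": t3,
        "true_death_day": np.where(np.asarray(death, bool), fu, np.inf),
    })


@pytest.fixture(scope="session")
def default_truth():
    """Ground truth of the reference configuration (assignment-free, so it
    is shared by the confounded and unconfounded variants)."""
    cfg = rwcea.default_config(seed=0)
    return rwcea.true_estimands(cfg, n_mc=150_000, seed=1001)


@pytest.fixture(scope="session")
def small_sim():
    """A study-scale simulated cohort with its cost matrices."""
    from rwcea.simulate import cost_matrices

    cfg = rwcea.default_config(seed=42)
    cohort = rwcea.generate_cohort(cfg)
    mats = cost_matrices(cohort, cfg)
    return cfg, cohort, mats
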