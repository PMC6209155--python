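"""Shared fixtures: small deterministic tables and the 50-seed recovery study."""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import biafs


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, seed 1 (the documented example cohort)."""
    return biafs.simulate_cohort(n=100, seed=1)


@pytest.fixture(scope="session")
def cohort_selection(cohort):
    """Default-config selection run on the seed-1 cohort."""
    table, truth = cohort
    result = biafs.run_selection(table, biafs.SelectionConfig(seed=1))
    return table, truth, result


@pytest.fixture()
def tiny_frame():
    """Hand-written 3-subject table (valid, all columns)."""
    return pd.DataFrame({
        "subject_id": ["a", "b", "c"],
        "R1": [300.0, 310.0, 290.0], "R2": [302.0, 308.0, 291.0],
        "R3": [30.0, 28.0, 32.0], "R4": [320.0, 330.0, 310.0],
        "R5": [321.0, 329.0, 312.0],
        "A": [30.0, 45.0, 60.0], "H": [170.0, 160.0, 175.0],
        "W": [70.0, 60.0, 80.0], "G": [1.0, 0.0, 1.0],
        "BFM": [18.0, 22.0, 25.0], "TBW": [40.0, 32.0, 44.0],
    })


@pytest.fixture()
def tiny_table(tiny_frame):
    return biafs.SampleTable(data=tiny_frame, band="250kHz", target_names=("BFM", "TBW"))


@dataclass
class SeedOutcome:
    seed: int
    report: biafs.RecoveryReport
    n_selected: int
    max_rel_err_selected: float
    max_rel_err_worst: float


@pytest.fixture(scope="session")
def recovery_study():
    """Fifty independent cohorts run through the default pipeline.

    For each seed: simulate n=100, select with the default config
    (alpha=0.20 permutation filter, 4 clusters, prune-farthest), score the
    recovery against ground truth, and fit held-out OLS models on the
    selected features and on the equally sized worst-ranked set.
    """
    outcomes = []
    for seed in range(50):
        table, truth = biafs.simulate_cohort(n=100, seed=seed)
        result = biafs.run_selection(table, biafs.SelectionConfig(seed=seed))
        report = biafs.recovery_report(result, truth)
        k = len(result.selected)
        worst = [s.feature_name for s in sorted(result.scores, key=lambda s: -s.rank)[:k]]
        train, test = biafs.split_train_test(table)
        Xtr = biafs.expand_features(train).to_frame()
        Xte = biafs.expand_features(test).to_frame()
        ytr, yte = train.target("BFM"), test.target("BFM")
        m_sel = biafs.fit_ols(Xtr[result.selected], ytr)
        m_worst = biafs.fit_ols(Xtr[worst], ytr)
        outcomes.append(SeedOutcome(
            seed=seed,
            report=report,
            n_selected=k,
            max_rel_err_selected=biafs.relative_errors(m_sel, Xte[result.selected], yte).max,
            max_rel_err_worst=biafs.relative_errors(m_worst, Xte[worst], yte).max,
        ))
    return outcomes
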