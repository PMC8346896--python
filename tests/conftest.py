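"""Shared fixtures: tiny handcrafted panels and cached default-model fits."""

import numpy as np
import pandas as pd
import pytest

import trajmix as tm


@pytest.fixture(scope="session")
def study_spec():
    return tm.default_study_spec()


@pytest.fixture(scope="session")
def sim1000(study_spec):
    """One default-model simulation reused by recovery/diagnostic tests."""
    panel, cov, labels = tm.simulate_panel(study_spec, 1000, seed=11)
    return panel, cov, labels


@pytest.fixture(scope="session")
def fit1000(sim1000):
    panel, _, _ = sim1000
    return tm.fit(panel, J=3, n_starts=3, seed=1)


@pytest.fixture(scope="session")
def covfit2000(study_spec):
    """Covariate-conditioned fit with standard errors at n=2000."""
    panel, cov, _ = tm.simulate_panel(study_spec, 2000, seed=21)
    model = tm.GroupTrajectoryModel(panel, 3, covariates=cov)
    return model.fit(n_starts=3, seed=2, compute_se=True)


@pytest.fixture
def tiny_panel():
    """Two persons observed at ages 17-18."""
    df = pd.DataFrame({
        "person_id": ["A", "A", "B", "B"],
        "cohort": ["y", "y", "o", "o"],
        "age": [17, 18, 17, 18],
        "count": [0, 2, 1, 0],
    })
    return tm.Panel(df)


def make_random_panel(rng, n_persons=8, with_charges=False):
    """Small random valid panel for property tests."""
    rows = []
    for i in range(n_persons):
        lo = int(rng.integers(10, 20))
        hi = lo + int(rng.integers(0, 6))
        cohort = str(rng.choice(["0", "9"]))
        for age in range(lo, hi + 1):
            count = int(rng.poisson(1.0))
            row = {"person_id": f"r{i:03d}", "cohort": cohort,
                   "age": age, "count": count}
            if with_charges:
                cats = rng.integers(0, count + 1, size=4)
                row.update({
                    "n_drugs": int(cats[0]), "n_violence": int(cats[1]),
                    "n_property": int(cats[2]), "n_other": int(cats[3]),
                })
            rows.append(row)
    return tm.Panel(pd.DataFrame(rows))
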