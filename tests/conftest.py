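import numpy as np
import pandas as pd
import pytest

from fibresub import DEFAULT_FIBRE_DENSITIES
from fibresub.defaults import survey_cohort_config
from fibresub.synthetic import generate_cohort


@pytest.fixture(scope="session")
def densities():
    return dict(DEFAULT_FIBRE_DENSITIES)


@pytest.fixture(scope="session")
def small_cohort():
    """Survey-calibrated cohort, small enough for fast tests."""
    cfg = survey_cohort_config(n_persons=300, seed=42)
    persons, events = generate_cohort(cfg)
    return cfg, persons, events


def make_persons(n, age_group="adult", sex="male"):
    """Minimal persons table with constant covariates."""
    return pd.DataFrame({
        "person_id": [f"P{i:04d}" for i in range(n)],
        "sex": sex,
        "age_group": age_group,
        "region": "eastern",
        "urbanisation": "rural",
        "education": "low",
        "employment": "employed",
        "income": "moderate",
        "ipaq": "moderate",
        "smoking": "non-smoker",
    })


def constant_white_bread_events(amounts, n_days=2):
    """Each person eats amounts[i] grams of white wheat bread every day."""
    rows = []
    for i, w in enumerate(amounts):
        for day in range(1, n_days + 1):
            if w > 0:
                rows.append({
                    "person_id": f"P{i:04d}", "recall_day": day,
                    "bread_category": "white_wheat", "amount": float(w),
                })
    return pd.DataFrame(rows, columns=["person_id", "recall_day", "bread_category", "amount"])


@pytest.fixture()
def noiseless_white_bread(densities):
    """Deterministic no-noise fixture: constant daily white-bread intake."""
    amounts = np.array([50.0, 80.0, 100.0, 120.0, 0.0, 150.0, 60.0, 90.0])
    persons = make_persons(len(amounts))
    events = constant_white_bread_events(amounts)
    return persons, events, amounts
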