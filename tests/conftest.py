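import numpy as np
import pandas as pd
import pytest

from prsfactor import PRSFactorModel, SimParams, simulate_cohort


@pytest.fixture(scope="session")
def sim20k():
    """Moderate synthetic cohort shared across read-only tests."""
    return simulate_cohort(SimParams(n_individuals=20_000, seed=7)).cohort


@pytest.fixture(scope="session")
def factor_results(sim20k):
    c = sim20k
    model = PRSFactorModel(
        c,
        strata={"smoking": c["smoking"].astype(bool),
                "hypertension": (c["sbp"] >= 140)},
        clinical_categories="category",
        seed=7,
    )
    return model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def tiny_cohort():
    """Hand-sized cohort table with every required column."""
    n = 30
    r = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "sex": r.integers(0, 2, n),
            "age": r.uniform(40, 69, n),
            "sbp": r.normal(135, 15, n),
            "total_chol": r.normal(5.8, 1.0, n),
            "hdl": r.uniform(0.8, 2.5, n),
            "smoking": r.integers(0, 2, n),
            "diabetes": r.integers(0, 2, n),
            "bmi": r.normal(27, 4, n),
            "bp_med": r.integers(0, 2, n),
            "lipid_med": r.integers(0, 2, n),
            "prevalent_cvd": r.integers(0, 2, n),
            "incident_cvd": r.integers(0, 2, n),
            "followup_years": r.uniform(0.5, 10, n),
        },
        index=pd.Index([f"id{i}" for i in range(n)], name="individual_id"),
    )
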