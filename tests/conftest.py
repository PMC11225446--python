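import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from jointglmm.schema import CANONICAL_COLUMNS

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_cohort(rows: list[dict]) -> pd.DataFrame:
    """Build a cohort frame from sparse row dicts, defaulting the rest."""
    defaults = {
        "gender": 0, "age": 35.0, "marital_status": 2, "weight": 57.0,
        "adherence": 1, "who_stage": 1, "functional_status": 1,
        "hemoglobin": 12.0, "baseline_cd4": 300, "religion": 1,
        "education": 3, "occupation": 0, "oi_status": 0, "regimen": 4,
        "cd4_count": 350, "tb_status": 1,
    }
    full = []
    for r in rows:
        row = {**defaults, **r}
        full.append(row)
    df = pd.DataFrame(full)
    for c in CANONICAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
        if c != "patient_id":
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return df[CANONICAL_COLUMNS]


@pytest.fixture
def tiny_cohort():
    """Three patients, three visits each, complete outcomes."""
    rows = []
    for p in range(1, 4):
        for v in range(1, 4):
            rows.append({
                "patient_id": f"P{p}", "visit": v,
                "cd4_count": 200 + 50 * p + 10 * v,
                "tb_status": (p + v) % 2,
                "weight": 50.0 + p, "hemoglobin": 10.0 + v,
            })
    return make_cohort(rows)


@pytest.fixture(scope="session")
def sim_cohort_small():
    """Simulated 150-patient cohort with the default truth."""
    from jointglmm import default_truth, simulate_cohort

    truth = default_truth(n_patients=150, max_visits=5, seed=42)
    cohort, truth = simulate_cohort(truth)
    return cohort, truth
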