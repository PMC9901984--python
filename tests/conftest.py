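import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def make_outcomes(n_dead, n_alive, start_id=0, age=65, index="2012-01-01"):
    """Outcome table with the first n_dead patients dead inside the horizon."""
    n = n_dead + n_alive
    pid = [f"P{start_id + i:05d}" for i in range(n)]
    index_ts = pd.Timestamp(index)
    death = [index_ts + pd.Timedelta(days=30)] * n_dead + [pd.NaT] * n_alive
    return pd.DataFrame(
        {
            "patient_id": pid,
            "index_date": index_ts,
            "death_date": pd.Series(death),
            "age": age,
        }
    )


def make_diagnoses(assignments, index="2012-01-01"):
    """Diagnosis table from (patient_id, canonical_code) pairs, dated pre-index."""
    date = pd.Timestamp(index) - pd.Timedelta(days=10)
    return pd.DataFrame(
        {
            "patient_id": [p for p, _ in assignments],
            "code": [c for _, c in assignments],
            "date": date,
        }
    )


@pytest.fixture
def toy_cohort():
    """10 patients (3 dead, 7 alive) with a handful of codes."""
    outcomes = make_outcomes(3, 7)
    diag = make_diagnoses(
        [
            ("P00000", "4275"),
            ("P00000", "4275"),  # duplicate record, must count once
            ("P00000", "5188"),
            ("P00001", "4275"),
            ("P00002", "25000"),
            ("P00003", "4275"),
            ("P00004", "25000"),
            ("P00005", "5188"),
            ("P00006", "25000"),
        ]
    )
    return diag, outcomes
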