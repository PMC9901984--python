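"""Synthetic diabetes-free primary-care cohorts with known disease effects.

The generator mirrors the multiplicative-odds structure the index
assumes: each patient independently acquires each disease with its
prevalence, and the patient's 6-month death odds are the baseline odds
multiplied by the odds multiplier of every acquired disease,

    odds_i = baseline_death_odds * prod over acquired d of true_effect_d,
    P(death within 183 days) = odds_i / (1 + odds_i).

Death dates fall uniformly inside the horizon, diagnosis dates uniformly
in the year before the shared index date.  Every draw comes from one
seeded generator, so a spec reproduces its cohort byte for byte.

Preset scenarios cover the study's qualitative contrasts: a ``null``
cohort with no signal, a ``recovery`` cohort for checking that fitted
LRs converge to the generating multipliers, a cohort whose mortality
signal sits on codes outside the Deyo-Charlson map (including rare codes
below the rollup threshold), and one whose signal is entirely on
Deyo-mapped codes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .charlson import default_condition_map
from .icd import parse_icd9
from .lr import DEFAULT_HORIZON_DAYS

__all__ = [
    "DiseaseSpec",
    "CohortSpec",
    "generate_cohort",
    "preset_scenarios",
    "SCENARIOS",
]

SCENARIOS = ("null", "recovery", "rare_signal_non_charlson", "charlson_only")

DEFAULT_INDEX_DATE = "2012-01-01"


def is_charlson(code: str) -> bool:
    """Whether a code falls inside the shipped Deyo condition map."""
    canon = parse_icd9(code).canonical_text
    cmap = default_condition_map()
    return any(
        canon.startswith(p) for cond in cmap.conditions.values() for p in cond.prefixes
    )


@dataclass(frozen=True)
class DiseaseSpec:
    """One simulated disease: its code, prevalence and true odds multiplier."""

    code: str
    prevalence: float
    true_effect: float
    in_charlson: Optional[bool] = None

    def __post_init__(self) -> None:
        parse_icd9(self.code)  # validates
        if not 0.0 < self.prevalence <= 1.0:
            raise ValueError(f"{self.code}: prevalence must be in (0, 1]")
        if not self.true_effect > 0.0:
            raise ValueError(f"{self.code}: true_effect must be > 0")
        if self.in_charlson is None:
            object.__setattr__(self, "in_charlson", is_charlson(self.code))


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; the seed is mandatory."""

    n_patients: int
    diseases: tuple[DiseaseSpec, ...]
    seed: int
    baseline_death_odds: float = 0.02
    age_range: tuple[int, int] = (60, 70)
    index_date: str = DEFAULT_INDEX_DATE
    horizon_days: int = DEFAULT_HORIZON_DAYS

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.diseases:
            raise ValueError("at least one disease required")
        if not self.baseline_death_odds > 0:
            raise ValueError("baseline_death_odds must be > 0")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be (low, high) with low < high")


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw a cohort: (diagnoses, outcomes, ground_truth).

    Diagnoses are long-format ``patient_id,icd9,date`` rows dated before
    the shared index date; outcomes are ``patient_id,index_date,
    death_date,age`` with a blank death date for survivors.  The ground
    truth records each disease's generating parameters and realized
    carrier counts.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_patients, len(spec.diseases)
    prevalence = np.array([ds.prevalence for ds in spec.diseases])
    effects = np.array([ds.true_effect for ds in spec.diseases])

    acquired = rng.random((n, d)) < prevalence[None, :]
    odds = spec.baseline_death_odds * np.prod(
        np.where(acquired, effects[None, :], 1.0), axis=1
    )
    p_death = odds / (1.0 + odds)
    dead = rng.random(n) < p_death
    death_offset = rng.integers(0, spec.horizon_days + 1, n)
    ages = rng.integers(spec.age_range[0], spec.age_range[1], n)

    pid = np.array([f"P{i:07d}" for i in range(n)])
    index = pd.Timestamp(spec.index_date)

    rows_i, rows_j = np.nonzero(acquired)
    diag_offset = rng.integers(1, 366, rows_i.size)
    codes = np.array([ds.code for ds in spec.diseases])
    diagnoses = pd.DataFrame(
        {
            "patient_id": pid[rows_i],
            "icd9": codes[rows_j],
            "date": index - pd.to_timedelta(diag_offset, unit="D"),
        }
    )
    death_date = pd.Series(index + pd.to_timedelta(death_offset, unit="D"))
    death_date[~dead] = pd.NaT
    outcomes = pd.DataFrame(
        {
            "patient_id": pid,
            "index_date": index,
            "death_date": death_date,
            "age": ages,
        }
    )
    carriers = acquired.sum(axis=0)
    dead_carriers = (acquired & dead[:, None]).sum(axis=0)
    ground_truth = {
        "n_patients": n,
        "seed": spec.seed,
        "baseline_death_odds": spec.baseline_death_odds,
        "horizon_days": spec.horizon_days,
        "n_dead": int(dead.sum()),
        "death_rate": float(dead.mean()),
        "diseases": [
            {
                "code": ds.code,
                "prevalence": ds.prevalence,
                "true_effect": ds.true_effect,
                "in_charlson": bool(ds.in_charlson),
                "n_carriers": int(carriers[j]),
                "n_dead_carriers": int(dead_carriers[j]),
                "realized_prevalence": float(carriers[j] / n),
            }
            for j, ds in enumerate(spec.diseases)
        ],
    }
    return diagnoses, outcomes, ground_truth


# Background codes with no mortality effect, spread over body systems.
_NOISE = (
    DiseaseSpec("401.9", 0.35, 1.0),   # essential hypertension
    DiseaseSpec("272.4", 0.25, 1.0),   # hyperlipidemia
    DiseaseSpec("715.90", 0.15, 1.0),  # osteoarthrosis
    DiseaseSpec("311", 0.12, 1.0),     # depressive disorder
    DiseaseSpec("530.81", 0.10, 1.0),  # esophageal reflux
    DiseaseSpec("493.90", 0.06, 1.0),  # asthma
    DiseaseSpec("729.5", 0.10, 1.0),   # pain in limb
    DiseaseSpec("V04.81", 0.20, 1.0),  # influenza vaccination encounter
)

_PRESETS: dict[str, tuple[int, tuple[DiseaseSpec, ...]]] = {
    # no signal anywhere: both indices should be uninformative
    "null": (
        20_000,
        (
            DiseaseSpec("401.9", 0.05, 1.0),
            DiseaseSpec("250.00", 0.05, 1.0),
            DiseaseSpec("715.90", 0.05, 1.0),
            DiseaseSpec("311", 0.05, 1.0),
            DiseaseSpec("493.90", 0.05, 1.0),
        ),
    ),
    # three effects {0.25, 1, 4} at 5% prevalence for LR recovery checks
    "recovery": (
        200_000,
        (
            DiseaseSpec("427.5", 0.05, 4.0),
            DiseaseSpec("250.00", 0.05, 1.0),
            DiseaseSpec("V70.0", 0.05, 0.25),
        ),
    ),
    # mortality signal on codes the Deyo map does not cover, including
    # rare codes (< 100 carriers at n = 100,000) that trigger rollup
    "rare_signal_non_charlson": (
        100_000,
        _NOISE
        + (
            DiseaseSpec("518.81", 0.030, 5.0),   # acute respiratory failure
            DiseaseSpec("486", 0.040, 2.5),      # pneumonia
            DiseaseSpec("584.9", 0.025, 3.5),    # acute kidney injury
            DiseaseSpec("038.9", 0.012, 4.0),    # septicemia
            DiseaseSpec("427.5", 0.006, 6.0),    # cardiac arrest
            DiseaseSpec("785.52", 0.005, 6.0),   # septic shock
            DiseaseSpec("V66.7", 0.005, 7.0),    # palliative care encounter
            DiseaseSpec("507.0", 0.008, 4.0),    # aspiration pneumonia
            DiseaseSpec("511.81", 0.004, 4.5),   # malignant pleural effusion
            DiseaseSpec("294.21", 0.010, 3.0),   # dementia w/ behavioral dist.
            DiseaseSpec("780.01", 0.0008, 9.0),  # coma (rare)
            DiseaseSpec("789.51", 0.0007, 7.0),  # malignant ascites (rare)
            DiseaseSpec("799.4", 0.0009, 6.0),   # cachexia (rare)
            DiseaseSpec("348.82", 0.0003, 12.0), # brain death (rare)
            # weak signal the DCI can see, so it is not pure noise
            DiseaseSpec("428.0", 0.060, 1.8),    # congestive heart failure
            DiseaseSpec("250.00", 0.100, 1.2),   # diabetes w/o complication
        ),
    ),
    # all signal on Deyo-mapped codes: both indices see the same diseases
    "charlson_only": (
        100_000,
        (
            DiseaseSpec("401.9", 0.35, 1.0),
            DiseaseSpec("715.90", 0.15, 1.0),
            DiseaseSpec("311", 0.12, 1.0),
            DiseaseSpec("530.81", 0.10, 1.0),
            DiseaseSpec("197.0", 0.008, 8.0),    # metastatic cancer of lung
            DiseaseSpec("428.0", 0.050, 3.0),    # congestive heart failure
            DiseaseSpec("410.1", 0.020, 2.5),    # acute myocardial infarction
            DiseaseSpec("585.6", 0.015, 3.5),    # end-stage renal disease
            DiseaseSpec("572.2", 0.004, 6.0),    # hepatic encephalopathy
            DiseaseSpec("162.9", 0.010, 4.0),    # malignant neoplasm of lung
            DiseaseSpec("290.0", 0.020, 3.0),    # senile dementia
            DiseaseSpec("496", 0.060, 1.8),      # chronic airway obstruction
            DiseaseSpec("042", 0.003, 3.0),      # HIV disease
        ),
    ),
}


def preset_scenarios(
    name: str, n_patients: Optional[int] = None, seed: int = 0
) -> CohortSpec:
    """A named scenario's :class:`CohortSpec`; ``n_patients`` overrides its default size."""
    if name not in _PRESETS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    default_n, diseases = _PRESETS[name]
    return CohortSpec(
        n_patients=n_patients or default_n,
        diseases=diseases,
        seed=seed,
    )
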