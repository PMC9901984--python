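"""Multimorbidity-index scoring.

A patient's diagnoses are mapped into the 19 body systems; within each
system only the worst disease — the one with the highest 6-month-mortality
likelihood ratio — is kept, every other diagnosis in that system is
ignored.  The patient's score is the product of the retained LRs,

    odds of mortality = prod over body systems b of LR(worst disease in b),

a relative mortality-odds score under the naive-Bayes reading of the LRs
(systems without any diagnosis contribute a factor of 1).  Log-odds are
reported alongside: they rank patients identically and are numerically
safer when many systems contribute.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .icd import BodySystem, ICD9Code, body_system_of
from .lr import LRTable

__all__ = [
    "PatientHistory",
    "MMIScore",
    "worst_per_system",
    "mmi_odds",
    "score_patient",
    "score_cohort",
    "build_histories",
    "scores_frame",
]

logger = logging.getLogger(__name__)

#: LR assigned to codes seen at scoring time but absent from training:
#: neutral, so the product stays well-defined without inventing risk.
UNSEEN_LR = 1.0


@dataclass(frozen=True)
class PatientHistory:
    """A patient's deduplicated diagnosis set on or before the index date."""

    patient_id: str
    codes: frozenset[ICD9Code]
    age: Optional[float] = None


@dataclass(frozen=True)
class MMIScore:
    """Per-system worst diseases and the multiplied odds score."""

    patient_id: str
    per_system: Mapping[BodySystem, tuple[ICD9Code, float]]
    odds: float
    log_odds: float
    calibrated_odds: Optional[float] = None


def worst_per_system(
    history: PatientHistory,
    lr_table: LRTable,
    overrides: Optional[Mapping[str, BodySystem]] = None,
) -> dict[BodySystem, tuple[ICD9Code, float]]:
    """Highest-LR code per body system represented in the history.

    Ties break to the lexicographically smallest canonical code text, for
    determinism.  Codes without an LR entry get the neutral LR of 1 and
    are logged.
    """
    chosen: dict[BodySystem, tuple[ICD9Code, float]] = {}
    for code in sorted(history.codes, key=lambda c: c.canonical_text):
        entry = lr_table.lookup(code)
        if entry is None:
            logger.warning(
                "code %s for patient %s absent from LR table; neutral LR=1 used",
                code.dotted,
                history.patient_id,
            )
            lr = UNSEEN_LR
        else:
            lr = entry.lr
        system = body_system_of(code, overrides)
        if system not in chosen or lr > chosen[system][1]:
            chosen[system] = (code, lr)
    return chosen


def mmi_odds(worst: Mapping[BodySystem, tuple[ICD9Code, float]]) -> float:
    """Product of the per-system worst-disease LRs; empty history scores 1."""
    odds = 1.0
    for _, lr in worst.values():
        if not lr > 0:
            raise ValueError("LRs must be strictly positive")
        odds *= lr
    return odds


def score_patient(
    history: PatientHistory,
    lr_table: LRTable,
    *,
    calibrated: bool = False,
    overrides: Optional[Mapping[str, BodySystem]] = None,
) -> MMIScore:
    """Score one patient.

    With ``calibrated=True`` the score is additionally reported as
    prior odds x product, using the training cohort's death odds as the
    prior; the raw product remains the primary score (identical ranking).
    """
    worst = worst_per_system(history, lr_table, overrides)
    odds = mmi_odds(worst)
    return MMIScore(
        patient_id=history.patient_id,
        per_system=worst,
        odds=odds,
        log_odds=math.log(odds),
        calibrated_odds=lr_table.prior_odds * odds if calibrated else None,
    )


def score_cohort(
    histories: Iterable[PatientHistory],
    lr_table: LRTable,
    *,
    calibrated: bool = False,
    overrides: Optional[Mapping[str, BodySystem]] = None,
) -> list[MMIScore]:
    """Score every patient; order-independent and deterministic."""
    return [
        score_patient(h, lr_table, calibrated=calibrated, overrides=overrides)
        for h in histories
    ]


def build_histories(
    diagnoses: pd.DataFrame,
    outcomes: pd.DataFrame,
    *,
    lookback_days: Optional[int] = None,
) -> list[PatientHistory]:
    """Assemble per-patient histories from the long diagnosis table.

    Every patient in *outcomes* yields a history (possibly empty); only
    diagnoses on or before the patient's index date, and within the
    optional lookback window, are included.  Codes are parsed canonicals
    from the reader, deduplicated here.
    """
    from .icd import parse_icd9  # local import to avoid cycle at module load

    diag = diagnoses.merge(
        outcomes[["patient_id", "index_date"]], on="patient_id", how="inner"
    )
    date = pd.to_datetime(diag["date"])
    idx = pd.to_datetime(diag["index_date"])
    keep = date <= idx
    if lookback_days is not None:
        keep &= (idx - date).dt.days <= lookback_days
    diag = diag.loc[keep]
    by_patient = diag.groupby("patient_id")["code"].agg(set)
    ages = outcomes.set_index("patient_id")["age"] if "age" in outcomes else None
    out = []
    for pid in outcomes["patient_id"]:
        codes = by_patient.get(pid, set())
        age = None
        if ages is not None and pd.notna(ages.at[pid]):
            age = float(ages.at[pid])
        out.append(
            PatientHistory(
                patient_id=str(pid),
                codes=frozenset(parse_icd9(c) for c in codes),
                age=age,
            )
        )
    return out


def scores_frame(scores: Iterable[MMIScore], explain: bool = False) -> pd.DataFrame:
    """Tabulate scores; ``explain`` adds per-system chosen code and LR columns."""
    rows = []
    for s in scores:
        row: dict = {"patient_id": s.patient_id, "odds": s.odds, "log_odds": s.log_odds}
        if s.calibrated_odds is not None:
            row["calibrated_odds"] = s.calibrated_odds
        if explain:
            for system, (code, lr) in sorted(
                s.per_system.items(), key=lambda kv: kv[0].name
            ):
                row[f"system_{system.name.lower()}_code"] = code.dotted
                row[f"system_{system.name.lower()}_lr"] = lr
        rows.append(row)
    return pd.DataFrame(rows)
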