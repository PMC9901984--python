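"""Estimation of per-diagnosis 6-month-mortality likelihood ratios.

For each diagnosis code observed in a training cohort the likelihood
ratio (LR) is the prevalence of the code among patients dead within the
horizon divided by its prevalence among survivors,

    LR = p(disease | dead within horizon) / p(disease | alive at horizon).

Two boundary rules keep every LR finite and positive: when all n carriers
of a code die the LR is taken as n + 1, and when all n survive it is
1 / (n + 1).  Codes carried by fewer than ``min_cases`` patients
(100 by default) inherit the LR of their broader ICD-9 concept: carriers
of all observed codes under the parent (4-digit) code are pooled, and if
that pool is still below the threshold the 3-digit category pool is used.
Rollup never crosses the 3-digit category boundary.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .icd import ICD9Code, parse_icd9

__all__ = [
    "CohortError",
    "DiagnosisCount",
    "LREntry",
    "LRTable",
    "label_outcomes",
    "count_diagnoses",
    "raw_lr",
    "rollup_rare",
    "fit_lr_table",
]

logger = logging.getLogger(__name__)

DEFAULT_HORIZON_DAYS = 183
DEFAULT_MIN_CASES = 100


class CohortError(ValueError):
    """Raised for cohorts on which LRs are undefined or inputs inconsistent."""


@dataclass(frozen=True)
class DiagnosisCount:
    """Patient-level carrier counts of one code in a labeled training cohort."""

    code: ICD9Code
    n_dead: int
    n_alive: int
    N_dead: int
    N_alive: int

    @property
    def n_total(self) -> int:
        return self.n_dead + self.n_alive

    def __post_init__(self) -> None:
        if not (0 <= self.n_dead <= self.N_dead and 0 <= self.n_alive <= self.N_alive):
            raise CohortError(f"inconsistent counts for {self.code}: {self}")


@dataclass(frozen=True)
class LREntry:
    """LR of one code, with rollup provenance.

    ``source_code`` is the code whose (possibly pooled) carriers produced
    the LR; it equals ``code`` when no rollup happened.  ``rollup_depth``
    counts ascent steps: 0 own counts, 1 parent pool, 2 category pool.
    """

    code: ICD9Code
    lr: float
    n_total: int
    source_code: ICD9Code
    rollup_depth: int


@dataclass
class LRTable:
    """Fitted LR table: one entry per code observed in training."""

    entries: dict[str, LREntry]
    horizon_days: int
    min_cases: int
    n_dead_total: int
    n_alive_total: int

    def lookup(self, code: ICD9Code) -> Optional[LREntry]:
        return self.entries.get(code.canonical_text)

    @property
    def prior_odds(self) -> float:
        """Training-cohort death odds, the prior of the naive-Bayes product."""
        return self.n_dead_total / self.n_alive_total

    def __len__(self) -> int:
        return len(self.entries)


def label_outcomes(
    outcomes: pd.DataFrame, horizon_days: int = DEFAULT_HORIZON_DAYS
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-patient 6-month-mortality labels.

    A patient is labeled dead iff a death date is present and falls within
    ``horizon_days`` of the index date (inclusive); a blank death date
    means alive, as does death after the horizon.  Rows with a death date
    strictly before the index date are invalid: they are excluded and
    returned in the second element for reporting.

    Parameters
    ----------
    outcomes : DataFrame with columns ``patient_id``, ``index_date``,
        ``death_date`` (datetime-like; NaT = alive).

    Returns
    -------
    (labels, excluded) : boolean Series indexed by patient_id, and the
        excluded invalid rows.
    """
    idx = pd.to_datetime(outcomes["index_date"])
    death = pd.to_datetime(outcomes["death_date"])
    delta = (death - idx).dt.days
    invalid = death.notna() & (delta < 0)
    if invalid.any():
        logger.warning(
            "%d outcome rows have death before index date; excluded", int(invalid.sum())
        )
    dead = death.notna() & (delta >= 0) & (delta <= horizon_days)
    labels = pd.Series(
        dead[~invalid].to_numpy(),
        index=pd.Index(outcomes.loc[~invalid, "patient_id"], name="patient_id"),
        name="dead",
    )
    return labels, outcomes.loc[invalid]


def _carrier_pairs(diagnoses: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Distinct (patient, code) pairs with the patient's label attached."""
    unlabeled = set(diagnoses["patient_id"]) - set(labels.index)
    if unlabeled:
        shown = sorted(map(str, unlabeled))[:10]
        raise CohortError(
            f"{len(unlabeled)} patients have diagnoses but no outcome row, "
            f"e.g. {shown}"
        )
    pairs = diagnoses[["patient_id", "code"]].drop_duplicates()
    pairs = pairs.assign(dead=labels.reindex(pairs["patient_id"]).to_numpy())
    return pairs


def count_diagnoses(
    diagnoses: pd.DataFrame, labels: pd.Series
) -> list[DiagnosisCount]:
    """Patient-level carrier counts for every distinct code.

    A patient contributes at most once to a code's dead or alive carrier
    count regardless of how many records of that code they have:
    prevalence is a per-patient concept.
    """
    pairs = _carrier_pairs(diagnoses, labels)
    N_dead = int(labels.sum())
    N_alive = int((~labels).sum())
    g = pairs.groupby("code")["dead"].agg(["sum", "size"])
    return [
        DiagnosisCount(
            code=parse_icd9(code),
            n_dead=int(row["sum"]),
            n_alive=int(row["size"] - row["sum"]),
            N_dead=N_dead,
            N_alive=N_alive,
        )
        for code, row in g.iterrows()
    ]


def raw_lr(count: DiagnosisCount) -> float:
    """Smoothed likelihood ratio of a single count record.

    Two-sided case: (n_dead/N_dead) / (n_alive/N_alive).  All carriers
    dead: n + 1.  All carriers alive: 1 / (n + 1).  Always finite and
    strictly positive.
    """
    if count.n_total == 0:
        raise CohortError(f"LR undefined for {count.code}: no carriers")
    if count.N_dead < 1 or count.N_alive < 1:
        raise CohortError(
            "LR undefined: training cohort needs at least one death and one survivor"
        )
    if count.n_alive == 0:
        return float(count.n_total + 1)
    if count.n_dead == 0:
        return 1.0 / (count.n_total + 1)
    return (count.n_dead / count.N_dead) / (count.n_alive / count.N_alive)


def _pooled_counts(pairs: pd.DataFrame, key: pd.Series) -> pd.DataFrame:
    """Patient-level dead/total counts pooled over a truncation key."""
    sub = pairs.assign(key=key).dropna(subset=["key"])
    sub = sub.drop_duplicates(["patient_id", "key"])
    g = sub.groupby("key")["dead"].agg(n_dead="sum", n_total="size")
    return g


def rollup_rare(
    pairs: pd.DataFrame,
    min_cases: int,
    N_dead: int,
    N_alive: int,
    trigger_counts: Optional[pd.Series] = None,
) -> dict[str, LREntry]:
    """Smoothed LRs for every observed code, rolling rare codes up the ontology.

    Parameters
    ----------
    pairs : distinct (patient_id, code, dead) rows — one per carrier.
    min_cases : carrier threshold below which a code inherits its broader
        concept's pooled LR.
    trigger_counts : optional per-code counts used only for the "<min_cases"
        trigger (e.g. raw record counts); defaults to patient carrier counts.

    The pool of a node is the union of carriers of all observed codes in
    its subtree, each patient counted once.  Subdivided codes ascend first
    to the 4-digit parent, then to the 3-digit category; the category pool
    is used even when still below the threshold.  Category-level codes
    have no broader within-category concept and keep their own LR.
    """
    counts = pairs.groupby("code")["dead"].agg(n_dead="sum", n_total="size")
    codes = {c: parse_icd9(c) for c in counts.index}

    cat_chars = {c: len(code.category_code.canonical_text) for c, code in codes.items()}
    code_col = pairs["code"]
    n_cat = code_col.map(cat_chars)
    key3 = code_col.map(lambda c: c[: cat_chars[c]])
    key4 = code_col.where(code_col.str.len() > n_cat).map(
        lambda c: c[: cat_chars[c] + 1], na_action="ignore"
    )
    agg4 = _pooled_counts(pairs, key4)
    agg3 = _pooled_counts(pairs, key3)

    entries: dict[str, LREntry] = {}
    for canonical, code in codes.items():
        n_dead = int(counts.at[canonical, "n_dead"])
        n_total = int(counts.at[canonical, "n_total"])
        trigger = n_total if trigger_counts is None else int(trigger_counts[canonical])
        chosen = DiagnosisCount(code, n_dead, n_total - n_dead, N_dead, N_alive)
        source, depth = code, 0
        if trigger < min_cases and code.depth > 3:
            k3 = code.category_code.canonical_text
            if code.depth == 5:
                k4 = canonical[: len(k3) + 1]
                pool = agg4.loc[k4]
                if int(pool["n_total"]) >= min_cases:
                    source, depth = code.parent(), 1
                else:
                    pool = agg3.loc[k3]
                    source, depth = code.category_code, 2
            else:
                pool = agg3.loc[k3]
                source, depth = code.category_code, 1
            chosen = DiagnosisCount(
                source,
                int(pool["n_dead"]),
                int(pool["n_total"] - pool["n_dead"]),
                N_dead,
                N_alive,
            )
        entries[canonical] = LREntry(
            code=code,
            lr=raw_lr(chosen),
            n_total=n_total,
            source_code=source,
            rollup_depth=depth,
        )
    return entries


def fit_lr_table(
    diagnoses: pd.DataFrame,
    outcomes: pd.DataFrame,
    *,
    horizon_days: int = DEFAULT_HORIZON_DAYS,
    min_cases: int = DEFAULT_MIN_CASES,
    lookback_days: Optional[int] = None,
    min_cases_unit: str = "patients",
) -> LRTable:
    """Fit the full LR table from a training cohort.

    Composition of outcome labeling, history restriction (diagnoses on or
    before the patient's index date, optionally within ``lookback_days``),
    patient-level counting and rare-code rollup.  Deterministic given its
    inputs.

    Raises
    ------
    CohortError
        On an empty training set or one with zero deaths or zero
        survivors overall (LRs undefined).
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    if min_cases_unit not in ("patients", "records"):
        raise ValueError("min_cases_unit must be 'patients' or 'records'")
    labels, _ = label_outcomes(outcomes, horizon_days)
    if labels.empty:
        raise CohortError("empty training cohort")
    if labels.index.has_duplicates:
        raise CohortError("duplicate patient_id in outcomes")
    N_dead, N_alive = int(labels.sum()), int((~labels).sum())
    if N_dead == 0 or N_alive == 0:
        raise CohortError(
            f"LRs undefined: training cohort has {N_dead} deaths and "
            f"{N_alive} survivors"
        )

    diag = diagnoses.merge(
        outcomes[["patient_id", "index_date"]], on="patient_id", how="inner"
    )
    date = pd.to_datetime(diag["date"])
    idx = pd.to_datetime(diag["index_date"])
    keep = date <= idx
    if lookback_days is not None:
        keep &= (idx - date).dt.days <= lookback_days
    diag = diag.loc[keep, ["patient_id", "code"]]
    if diag.empty:
        raise CohortError("no diagnoses fall in the history window")
    # normalize spellings so dotted and undotted input share one entry
    canon = {c: parse_icd9(c).canonical_text for c in diag["code"].unique()}
    diag = diag.assign(code=diag["code"].map(canon))

    pairs = _carrier_pairs(diag, labels)
    trigger = diag.groupby("code").size() if min_cases_unit == "records" else None
    entries = rollup_rare(pairs, min_cases, N_dead, N_alive, trigger_counts=trigger)
    return LRTable(
        entries=entries,
        horizon_days=horizon_days,
        min_cases=min_cases,
        n_dead_total=N_dead,
        n_alive_total=N_alive,
    )
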