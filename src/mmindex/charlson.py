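"""Deyo adaptation of the Charlson comorbidity index (DCI).

Seventeen clinician-selected conditions are flagged from ICD-9-CM codes
by prefix matching, weighted with the original Charlson weights
(1, 2, 3 or 6), and summed together with age points (one point per
decade from age 50, capped at 4 from age 80).  The shipped condition map
is a versioned transcription of the published Deyo ICD-9-CM adaptation
and can be replaced by a user file with the same layout.

Three severity hierarchies apply: mild liver disease is suppressed by
moderate/severe liver disease, uncomplicated diabetes by diabetes with
chronic complications, and any malignancy by metastatic solid tumor.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd

from .scoring import PatientHistory

__all__ = [
    "DeyoCondition",
    "DeyoConditionMap",
    "DCIScore",
    "default_condition_map",
    "map_conditions",
    "age_points",
    "dci_score",
    "score_cohort_dci",
    "dci_frame",
]

#: (suppressed, suppressor) severity pairs.
HIERARCHY = (
    ("mild_liver_disease", "moderate_severe_liver_disease"),
    ("diabetes_without_complications", "diabetes_with_complications"),
    ("any_malignancy", "metastatic_solid_tumor"),
)

_N_CONDITIONS = 17


@dataclass(frozen=True)
class DeyoCondition:
    name: str
    weight: int
    prefixes: tuple[str, ...]  # canonical (undotted) code prefixes


class DeyoConditionMap:
    """The 17 Deyo conditions with their code prefixes and weights."""

    def __init__(self, conditions: Iterable[DeyoCondition], strict: bool = True):
        self.conditions: dict[str, DeyoCondition] = {c.name: c for c in conditions}
        if strict and len(self.conditions) != _N_CONDITIONS:
            raise ValueError(
                f"expected {_N_CONDITIONS} conditions, got {len(self.conditions)}"
            )
        for c in self.conditions.values():
            if c.weight not in (1, 2, 3, 6):
                raise ValueError(f"condition {c.name}: weight {c.weight} not in 1/2/3/6")

    @classmethod
    def from_csv(cls, path, strict: bool = True) -> "DeyoConditionMap":
        """Load a `condition,weight,code_prefixes` file (prefixes ;-separated)."""
        frame = pd.read_csv(path, dtype={"condition": str, "code_prefixes": str})
        missing = {"condition", "weight", "code_prefixes"} - set(frame.columns)
        if missing:
            raise ValueError(f"condition map lacks columns: {sorted(missing)}")
        conditions = []
        for _, row in frame.iterrows():
            prefixes = tuple(
                _canonical_prefix(p) for p in str(row["code_prefixes"]).split(";") if p
            )
            conditions.append(
                DeyoCondition(str(row["condition"]), int(row["weight"]), prefixes)
            )
        return cls(conditions, strict=strict)

    def names(self) -> list[str]:
        return list(self.conditions)


def _canonical_prefix(text: str) -> str:
    """Undotted uppercase prefix; dotted input allowed (``"443.9"`` -> ``"4439"``)."""
    return text.strip().upper().replace(".", "")


def default_condition_map() -> DeyoConditionMap:
    """The shipped Deyo 17-condition map."""
    with resources.as_file(
        resources.files("mmindex.data").joinpath("deyo_charlson.csv")
    ) as p:
        return DeyoConditionMap.from_csv(p)


@dataclass(frozen=True)
class DCIScore:
    patient_id: str
    flags: Mapping[str, bool]
    comorbidity_points: int
    age_points: int

    @property
    def total(self) -> int:
        return self.comorbidity_points + self.age_points


def map_conditions(
    history: PatientHistory, cmap: Optional[DeyoConditionMap] = None
) -> dict[str, bool]:
    """Flag each Deyo condition present in the history.

    A condition is present iff any history code's canonical text starts
    with one of its prefixes; severity hierarchies are then applied so
    that at most one member of each pair stays flagged.
    """
    cmap = cmap or default_condition_map()
    texts = [c.canonical_text for c in history.codes]
    flags = {
        name: any(t.startswith(p) for t in texts for p in cond.prefixes)
        for name, cond in cmap.conditions.items()
    }
    for mild, severe in HIERARCHY:
        if flags.get(mild) and flags.get(severe):
            flags[mild] = False
    return flags


def age_points(age: float) -> int:
    """Charlson age points: 0 below 50, 1 per decade, capped at 4 from 80."""
    if age < 0:
        raise ValueError(f"negative age: {age}")
    if age < 50:
        return 0
    return min(4, 1 + int((age - 50) // 10))


def dci_score(
    flags: Mapping[str, bool],
    age: float,
    cmap: Optional[DeyoConditionMap] = None,
    patient_id: str = "",
) -> DCIScore:
    """Weighted sum of flagged conditions plus age points."""
    cmap = cmap or default_condition_map()
    comorbidity = sum(cmap.conditions[name].weight for name, on in flags.items() if on)
    return DCIScore(
        patient_id=patient_id,
        flags=dict(flags),
        comorbidity_points=int(comorbidity),
        age_points=age_points(age),
    )


def score_cohort_dci(
    histories: Iterable[PatientHistory], cmap: Optional[DeyoConditionMap] = None
) -> list[DCIScore]:
    """DCI for every patient; missing age contributes 0 age points."""
    cmap = cmap or default_condition_map()
    out = []
    for h in histories:
        flags = map_conditions(h, cmap)
        out.append(
            dci_score(flags, h.age if h.age is not None else 0.0, cmap, h.patient_id)
        )
    return out


def dci_frame(scores: Iterable[DCIScore], explain: bool = False) -> pd.DataFrame:
    """Tabulate DCI scores; ``explain`` adds one boolean column per condition."""
    rows = []
    for s in scores:
        row: dict = {
            "patient_id": s.patient_id,
            "total": s.total,
            "comorbidity_points": s.comorbidity_points,
            "age_points": s.age_points,
        }
        if explain:
            for name, on in s.flags.items():
                row[f"flag_{name}"] = bool(on)
        rows.append(row)
    return pd.DataFrame(rows)
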