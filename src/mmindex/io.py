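"""Readers and writers for the delimited-text artifacts, and run configuration.

All artifacts are plain CSV (UTF-8, day-resolution ISO-8601 dates):
diagnoses, outcomes, the fitted LR table (with a commented header block
carrying its parameters), score tables, and JSON reports/manifests.
Likelihood ratios are written with full double precision so that a
write/read round trip is lossless.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .icd import ICD9ParseError, parse_icd9
from .lr import DEFAULT_HORIZON_DAYS, DEFAULT_MIN_CASES, LREntry, LRTable

__all__ = [
    "IOValidationError",
    "ReadResult",
    "RunConfig",
    "read_diagnoses",
    "read_outcomes",
    "write_lr_table",
    "read_lr_table",
    "write_json",
    "build_manifest",
]

#: fraction of malformed rows above which a read is fatal
MAX_BAD_FRACTION = 0.10


class IOValidationError(ValueError):
    """Fatal problem with an input file (structure or too many bad rows)."""


@dataclass
class ReadResult:
    """A loaded table plus the rows rejected or flagged during validation."""

    frame: pd.DataFrame
    rejected: pd.DataFrame

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class RunConfig:
    """Thresholds and options of a full pipeline run."""

    horizon_days: int = DEFAULT_HORIZON_DAYS
    min_cases: int = DEFAULT_MIN_CASES
    train_fraction: float = 0.9
    seed: int = 0
    lookback_days: Optional[int] = None
    calibrated: bool = False
    explain: bool = False
    ci_method: str = "delong"

    def __post_init__(self) -> None:
        if self.horizon_days <= 0 or self.min_cases <= 0:
            raise ValueError("horizon_days and min_cases must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.lookback_days is not None and self.lookback_days <= 0:
            raise ValueError("lookback_days must be positive when set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise IOValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _require_columns(frame: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(frame.columns)
    if missing:
        raise IOValidationError(f"{path}: missing columns {sorted(missing)}")


def read_diagnoses(path) -> ReadResult:
    """Load a `patient_id,icd9,date` diagnosis file.

    Codes are normalized to canonical undotted form in a ``code`` column;
    malformed codes or dates reject the row (collected with line numbers
    and reasons).  More than 10% rejected rows is fatal.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, {"patient_id", "icd9", "date"}, path)
    reasons = pd.Series("", index=raw.index)

    def _canon(tok: str) -> str:
        try:
            return parse_icd9(tok).canonical_text
        except ICD9ParseError:
            return ""

    code = raw["icd9"].map(_canon)
    reasons[code == ""] = "unparseable ICD-9 code"
    date = pd.to_datetime(raw["date"], errors="coerce")
    reasons[(reasons == "") & date.isna()] = "unparseable date"

    bad = reasons != ""
    rejected = raw.loc[bad].assign(line=raw.index[bad] + 2, reason=reasons[bad])
    if len(raw) and len(rejected) / len(raw) > MAX_BAD_FRACTION:
        raise IOValidationError(
            f"{path}: {len(rejected)}/{len(raw)} rows malformed "
            f"(> {MAX_BAD_FRACTION:.0%}); first: "
            f"{rejected[['line', 'icd9', 'reason']].head(5).to_dict('records')}"
        )
    frame = pd.DataFrame(
        {
            "patient_id": raw.loc[~bad, "patient_id"],
            "code": code[~bad],
            "date": date[~bad],
        }
    ).reset_index(drop=True)
    return ReadResult(frame=frame, rejected=rejected.reset_index(drop=True))


def read_outcomes(path) -> ReadResult:
    """Load a `patient_id,index_date,death_date,age` outcomes file.

    A blank death date means the patient is alive.  Duplicate patient ids
    are fatal; unparseable dates reject the row; a death date before the
    index date is flagged here and excluded later during labeling.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, {"patient_id", "index_date", "death_date", "age"}, path)
    dupes = raw["patient_id"][raw["patient_id"].duplicated()]
    if len(dupes):
        raise IOValidationError(
            f"{path}: duplicate patient_id values, e.g. {dupes.head(5).tolist()}"
        )
    reasons = pd.Series("", index=raw.index)
    index_date = pd.to_datetime(raw["index_date"], errors="coerce")
    reasons[index_date.isna()] = "unparseable index_date"
    nonblank = raw["death_date"].str.strip() != ""
    death_date = pd.to_datetime(
        raw["death_date"].where(nonblank, None), errors="coerce"
    )
    reasons[(reasons == "") & nonblank & death_date.isna()] = "unparseable death_date"
    age = pd.to_numeric(raw["age"], errors="coerce")
    reasons[(reasons == "") & age.isna() & (raw["age"].str.strip() != "")] = (
        "unparseable age"
    )
    reasons[(reasons == "") & (age < 0)] = "negative age"
    flagged = (reasons == "") & death_date.notna() & (death_date < index_date)
    reasons[flagged] = "death_date before index_date (flagged; excluded at labeling)"

    bad = (reasons != "") & ~flagged
    report = reasons != ""
    rejected = raw.loc[report].assign(line=raw.index[report] + 2, reason=reasons[report])
    keep = ~bad
    frame = pd.DataFrame(
        {
            "patient_id": raw.loc[keep, "patient_id"],
            "index_date": index_date[keep],
            "death_date": death_date[keep],
            "age": age[keep],
        }
    ).reset_index(drop=True)
    return ReadResult(frame=frame, rejected=rejected.reset_index(drop=True))


def write_lr_table(table: LRTable, path) -> None:
    """Write the LR table CSV with a commented parameter header."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("# mmindex lr_table v1\n")
        fh.write(f"# horizon_days={table.horizon_days}\n")
        fh.write(f"# min_cases={table.min_cases}\n")
        fh.write(f"# n_dead={table.n_dead_total}\n")
        fh.write(f"# n_alive={table.n_alive_total}\n")
        fh.write("code,lr,n_total,source_code,rollup_depth\n")
        for canonical in sorted(table.entries):
            e = table.entries[canonical]
            fh.write(
                f"{e.code.dotted},{e.lr!r},{e.n_total},"
                f"{e.source_code.dotted},{e.rollup_depth}\n"
            )


def read_lr_table(path) -> LRTable:
    """Read an LR table written by :func:`write_lr_table` (lossless)."""
    meta: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line[1:].strip()
            if "=" in text:
                key, _, value = text.partition("=")
                meta[key.strip()] = int(value)
    required = {"horizon_days", "min_cases", "n_dead", "n_alive"}
    if required - set(meta):
        raise IOValidationError(
            f"{path}: LR-table header lacks {sorted(required - set(meta))}"
        )
    frame = pd.read_csv(path, comment="#", dtype={"code": str, "source_code": str})
    entries = {}
    for row in frame.itertuples(index=False):
        code = parse_icd9(row.code)
        entries[code.canonical_text] = LREntry(
            code=code,
            lr=float(row.lr),
            n_total=int(row.n_total),
            source_code=parse_icd9(row.source_code),
            rollup_depth=int(row.rollup_depth),
        )
    return LRTable(
        entries=entries,
        horizon_days=meta["horizon_days"],
        min_cases=meta["min_cases"],
        n_dead_total=meta["n_dead"],
        n_alive_total=meta["n_alive"],
    )


def write_json(obj: dict, path) -> None:
    """Deterministic JSON: sorted keys, stable float repr, trailing newline."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(config: RunConfig, inputs: dict[str, Path]) -> dict:
    """Reproducibility manifest: config, seed and input checksums."""
    from . import __version__

    return {
        "mmindex_version": __version__,
        "config": config.to_dict(),
        "inputs": {name: sha256_of(p) for name, p in sorted(inputs.items())},
    }
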