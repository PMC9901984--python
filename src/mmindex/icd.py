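"""ICD-9-CM code handling.

Parsing and normalization of ICD-9-CM diagnosis codes, the 3/4/5-digit
code hierarchy used for rare-code rollup, and the assignment of every
code to one of 19 body systems (the 17 numeric chapters of ICD-9-CM plus
the E-code and V-code supplementary classifications).
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "ICD9ParseError",
    "ICD9Code",
    "BodySystem",
    "BODY_SYSTEM_RANGES",
    "parse_icd9",
    "parent_of",
    "descendants_of",
    "body_system_of",
    "load_body_system_overrides",
]


class ICD9ParseError(ValueError):
    """Raised when a token cannot be read as an ICD-9-CM code."""


class BodySystem(Enum):
    """The 19 body systems: ICD-9-CM chapters plus E and V codes."""

    INFECTIOUS = "infectious and parasitic diseases"
    NEOPLASMS = "neoplasms"
    ENDOCRINE = "endocrine, nutritional, metabolic and immunity disorders"
    BLOOD = "diseases of the blood and blood-forming organs"
    MENTAL = "mental disorders"
    NERVOUS = "diseases of the nervous system and sense organs"
    CIRCULATORY = "diseases of the circulatory system"
    RESPIRATORY = "diseases of the respiratory system"
    DIGESTIVE = "diseases of the digestive system"
    GENITOURINARY = "diseases of the genitourinary system"
    PREGNANCY = "complications of pregnancy, childbirth and the puerperium"
    SKIN = "diseases of the skin and subcutaneous tissue"
    MUSCULOSKELETAL = "diseases of the musculoskeletal system and connective tissue"
    CONGENITAL = "congenital anomalies"
    PERINATAL = "conditions originating in the perinatal period"
    ILL_DEFINED = "symptoms, signs and ill-defined conditions"
    INJURY = "injury and poisoning"
    EXTERNAL = "external causes of injury (E codes)"
    SOCIAL = "social determinants of illness (V codes)"


#: Inclusive 3-digit category ranges for the 17 numeric chapters; E and V
#: flavors are their own systems.  Ranges are disjoint and cover 001-999.
BODY_SYSTEM_RANGES: tuple[tuple[int, int, BodySystem], ...] = (
    (1, 139, BodySystem.INFECTIOUS),
    (140, 239, BodySystem.NEOPLASMS),
    (240, 279, BodySystem.ENDOCRINE),
    (280, 289, BodySystem.BLOOD),
    (290, 319, BodySystem.MENTAL),
    (320, 389, BodySystem.NERVOUS),
    (390, 459, BodySystem.CIRCULATORY),
    (460, 519, BodySystem.RESPIRATORY),
    (520, 579, BodySystem.DIGESTIVE),
    (580, 629, BodySystem.GENITOURINARY),
    (630, 679, BodySystem.PREGNANCY),
    (680, 709, BodySystem.SKIN),
    (710, 739, BodySystem.MUSCULOSKELETAL),
    (740, 759, BodySystem.CONGENITAL),
    (760, 779, BodySystem.PERINATAL),
    (780, 799, BodySystem.ILL_DEFINED),
    (800, 999, BodySystem.INJURY),
)


@dataclass(frozen=True, order=True)
class ICD9Code:
    """A normalized ICD-9-CM code.

    Attributes
    ----------
    flavor : str
        ``"numeric"``, ``"E"`` or ``"V"``.
    category : str
        Digits of the 3-digit category stem, zero-padded (3 digits for
        numeric and E codes, 2 for V codes).
    subdivision : str
        0-2 further digits beyond the category.
    """

    flavor: str
    category: str
    subdivision: str = ""

    @property
    def canonical_text(self) -> str:
        """Undotted normalized spelling, e.g. ``"4275"``, ``"E999"``, ``"V667"``."""
        prefix = "" if self.flavor == "numeric" else self.flavor
        return f"{prefix}{self.category}{self.subdivision}"

    @property
    def dotted(self) -> str:
        """Conventional dotted spelling, e.g. ``"427.5"``."""
        prefix = "" if self.flavor == "numeric" else self.flavor
        if self.subdivision:
            return f"{prefix}{self.category}.{self.subdivision}"
        return f"{prefix}{self.category}"

    @property
    def depth(self) -> int:
        """3 for a bare category, 4 or 5 with subdivision digits."""
        return 3 + len(self.subdivision)

    @property
    def category_code(self) -> "ICD9Code":
        """The 3-digit category at the top of this code's hierarchy."""
        if not self.subdivision:
            return self
        return ICD9Code(self.flavor, self.category)

    def parent(self) -> Optional["ICD9Code"]:
        """The code with one trailing subdivision digit removed; None at depth 3."""
        if not self.subdivision:
            return None
        return ICD9Code(self.flavor, self.category, self.subdivision[:-1])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.dotted


def _fail(raw: str, why: str) -> None:
    raise ICD9ParseError(f"cannot parse ICD-9 code {raw!r}: {why}")


@lru_cache(maxsize=65536)
def parse_icd9(raw: str) -> ICD9Code:
    """Parse a dotted or undotted ICD-9-CM code spelling.

    Both spellings of the same code normalize to the same :class:`ICD9Code`
    (``"427.5"`` == ``"4275"``); trailing dots are ignored and numeric
    categories are zero-padded to 3 digits (``"38.12"`` -> ``038.12``).
    Undotted numeric strings are read with a 3-digit category, the ICD-9-CM
    convention (``"3812"`` -> ``381.2``).

    Raises
    ------
    ICD9ParseError
        For empty input, letters other than a leading E/V, more than two
        subdivision digits, or an over-long category stem.  ICD-10-style
        codes (any other leading letter) are rejected with the same error.
    """
    if not isinstance(raw, str):
        _fail(raw, "not text")
    tok = raw.strip().upper()
    if not tok:
        _fail(raw, "empty")
    flavor = "numeric"
    body = tok
    if body[0].isalpha():
        if body[0] in ("E", "V"):
            flavor = body[0]
            body = body[1:]
        else:
            _fail(raw, f"unexpected letter {body[0]!r} (ICD-10 codes are not supported)")
    cat_len = 2 if flavor == "V" else 3
    if "." in body:
        stem, _, sub = body.partition(".")
        if "." in sub:
            _fail(raw, "more than one dot")
    else:
        stem, sub = body[:cat_len], body[cat_len:]
    if not stem:
        _fail(raw, "empty category")
    if not stem.isdigit():
        _fail(raw, "category is not numeric")
    if len(stem) > cat_len:
        _fail(raw, f"category longer than {cat_len} digits")
    if sub and not sub.isdigit():
        _fail(raw, "subdivision is not numeric")
    if len(sub) > 2:
        _fail(raw, "more than 2 subdivision digits")
    return ICD9Code(flavor, stem.zfill(cat_len), sub)


def parent_of(code: ICD9Code) -> Optional[ICD9Code]:
    """Broader concept one level up the hierarchy (None for 3-digit codes)."""
    return code.parent()


def descendants_of(code: ICD9Code, universe: Iterable[ICD9Code]) -> set[ICD9Code]:
    """Codes in *universe* whose truncation chain passes through *code*.

    Includes *code* itself when observed.  This is the set whose carriers
    are pooled when a rare code inherits the likelihood ratio of its
    broader concept.
    """
    return {
        u
        for u in universe
        if u.flavor == code.flavor
        and u.category == code.category
        and u.subdivision.startswith(code.subdivision)
    }


def body_system_of(
    code: ICD9Code,
    overrides: Optional[Mapping[str, BodySystem]] = None,
) -> BodySystem:
    """Body system of a code, determined by its 3-digit category.

    E-flavor codes map to external causes, V-flavor to social determinants,
    numeric categories through the chapter ranges of
    :data:`BODY_SYSTEM_RANGES`.  *overrides* optionally re-bins specific
    categories, keyed by the category's canonical text (e.g. ``"038"``,
    ``"V66"``).
    """
    if overrides:
        hit = overrides.get(code.category_code.canonical_text)
        if hit is not None:
            return hit
    if code.flavor == "E":
        return BodySystem.EXTERNAL
    if code.flavor == "V":
        return BodySystem.SOCIAL
    n = int(code.category)
    for lo, hi, system in BODY_SYSTEM_RANGES:
        if lo <= n <= hi:
            return system
    # category "000" is the only 3-digit string outside 001-999
    raise ICD9ParseError(f"numeric category {code.category!r} outside 001-999")


_LABELS = {s.value.lower(): s for s in BodySystem} | {s.name.lower(): s for s in BodySystem}


def load_body_system_overrides(path) -> dict[str, BodySystem]:
    """Load a `category,system_name` delimited file re-binning categories.

    System names may be enum names (``CIRCULATORY``) or full labels; the
    mapping is validated for parseable categories and for uniqueness.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = {"category", "system_name"} - set(frame.columns)
    if missing:
        raise ValueError(f"override file {path} lacks columns: {sorted(missing)}")
    out: dict[str, BodySystem] = {}
    for _, row in frame.iterrows():
        cat = parse_icd9(str(row["category"]).strip()).category_code.canonical_text
        name = str(row["system_name"]).strip().lower()
        if name not in _LABELS:
            raise ValueError(f"unknown body system {row['system_name']!r}")
        if cat in out:
            raise ValueError(f"category {cat!r} mapped twice in override file")
        out[cat] = _LABELS[name]
    return out
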