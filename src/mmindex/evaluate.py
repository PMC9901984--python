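"""Train/validation splitting and ROC/AUC evaluation.

AUC is the Mann-Whitney pair statistic — the probability that a randomly
chosen patient who died ranks above a randomly chosen survivor, with
ties credited 0.5 — computed from midranks.  Confidence intervals and
the paired two-index comparison use the DeLong placement-variance
estimator (analytic and deterministic); a seeded bootstrap is available
as an alternative CI method.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "SplitSpec",
    "AUCResult",
    "ROCCurve",
    "AUCComparison",
    "split_cohort",
    "auc",
    "roc_curve",
    "compare_auc",
]


@dataclass(frozen=True)
class SplitSpec:
    """Patient-level train/validation split: fraction for training, seed."""

    train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_cohort(
    patient_ids: Sequence,
    spec: SplitSpec,
    labels: Optional[Sequence[bool]] = None,
    stratify: bool = False,
) -> tuple[list, list]:
    """Disjoint, exhaustive, reproducible patient-level split.

    Sizes are within one patient of the exact fractions.  With *labels*
    supplied, a training side containing only deaths or only survivors is
    rejected (LRs would be undefined there); ``stratify=True`` splits
    within each outcome class separately.
    """
    ids = list(patient_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate patient ids")
    rng = np.random.default_rng(spec.seed)
    if stratify:
        if labels is None:
            raise ValueError("stratified split needs labels")
        lab = np.asarray(labels, dtype=bool)
        train, valid = [], []
        for cls in (False, True):
            cls_ids = [i for i, l in zip(ids, lab) if l == cls]
            perm = rng.permutation(len(cls_ids))
            k = round(spec.train_fraction * len(cls_ids))
            train += [cls_ids[j] for j in perm[:k]]
            valid += [cls_ids[j] for j in perm[k:]]
    else:
        perm = rng.permutation(len(ids))
        k = round(spec.train_fraction * len(ids))
        train = [ids[j] for j in perm[:k]]
        valid = [ids[j] for j in perm[k:]]
    if not train or not valid:
        raise ValueError("split left one side empty; adjust train_fraction or n")
    if labels is not None:
        lab_map = dict(zip(ids, np.asarray(labels, dtype=bool)))
        train_labels = {lab_map[i] for i in train}
        if len(train_labels) < 2:
            raise ValueError(
                "training split has a single outcome class; re-seed or enlarge cohort"
            )
    return train, valid


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    method: str
    se: float


def _check_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d and aligned")
    if y.all() or not y.any():
        raise ValueError("labels must contain both classes")
    return s, y


def _placements(s: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values for positives (V10) and negatives (V01)."""
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    r_all = rankdata(s)
    r_pos = rankdata(s[y])
    r_neg = rankdata(s[~y])
    v10 = (r_all[y] - r_pos) / n_neg
    v01 = 1.0 - (r_all[~y] - r_neg) / n_pos
    return float(v10.mean()), v10, v01


def auc(
    scores,
    labels,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> AUCResult:
    """AUC with a 95% confidence interval.

    ``method="delong"`` (default) uses the analytic placement variance;
    ``method="bootstrap"`` resamples patients ``n_boot`` times with the
    given seed and takes percentile bounds.
    """
    s, y = _check_labels(scores, labels)
    a, v10, v01 = _placements(s, y)
    n_pos, n_neg = len(v10), len(v01)
    var = 0.0
    if n_pos > 1:
        var += np.var(v10, ddof=1) / n_pos
    if n_neg > 1:
        var += np.var(v01, ddof=1) / n_neg
    se = float(np.sqrt(var))
    z = norm.ppf(1 - alpha / 2)
    if method == "delong":
        lo, hi = a - z * se, a + z * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = len(s)
        stats = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.all() or not yb.any():
                continue
            stats.append(_placements(s[idx], yb)[0])
        lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return AUCResult(
        auc=a,
        ci_low=float(min(max(lo, 0.0), a)),
        ci_high=float(max(min(hi, 1.0), a)),
        n_pos=n_pos,
        n_neg=n_neg,
        method=method,
        se=se,
    )


@dataclass(frozen=True)
class ROCCurve:
    """ROC points: thresholds descending, sensitivity rising to 1, specificity falling."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def area(self) -> float:
        """Trapezoidal area in (1 - specificity, sensitivity) space."""
        return float(np.trapezoid(self.sensitivity, 1.0 - self.specificity))


def roc_curve(scores, labels) -> ROCCurve:
    """Full ROC curve, one point per distinct threshold plus both endpoints.

    The trapezoidal area under the returned curve equals the midrank AUC.
    """
    s, y = _check_labels(scores, labels)
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    return ROCCurve(thresholds=thr, sensitivity=tpr, specificity=1.0 - fpr)


@dataclass(frozen=True)
class AUCComparison:
    """Paired DeLong comparison of two indices on the same patients."""

    auc_a: float
    auc_b: float
    delta: float
    ci_low: float
    ci_high: float
    p_value: float
    se: float

    @property
    def relative_improvement(self) -> float:
        """delta / auc_b — the relative gain of index a over index b."""
        return self.delta / self.auc_b


def compare_auc(scores_a, scores_b, labels, alpha: float = 0.05) -> AUCComparison:
    """DeLong test for the difference of two correlated AUCs.

    Both score vectors must cover the same patients in the same order.
    Returns the AUC difference a - b, its 95% CI and the two-sided p.
    """
    sa, y = _check_labels(scores_a, labels)
    sb, y2 = _check_labels(scores_b, labels)
    if len(sa) != len(sb):
        raise ValueError("score vectors cover different patient sets")
    auc_a, v10a, v01a = _placements(sa, y)
    auc_b, v10b, v01b = _placements(sb, y)
    n_pos, n_neg = len(v10a), len(v01a)

    def _var(v10, v01):
        out = 0.0
        if n_pos > 1:
            out += np.var(v10, ddof=1) / n_pos
        if n_neg > 1:
            out += np.var(v01, ddof=1) / n_neg
        return out

    cov = 0.0
    if n_pos > 1:
        cov += np.cov(v10a, v10b, ddof=1)[0, 1] / n_pos
    if n_neg > 1:
        cov += np.cov(v01a, v01b, ddof=1)[0, 1] / n_neg
    var_delta = _var(v10a, v01a) + _var(v10b, v01b) - 2.0 * cov
    delta = auc_a - auc_b
    se = float(np.sqrt(max(var_delta, 0.0)))
    z_crit = norm.ppf(1 - alpha / 2)
    if se == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        p = float(2.0 * norm.sf(abs(delta) / se))
    return AUCComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        delta=delta,
        ci_low=delta - z_crit * se,
        ci_high=delta + z_crit * se,
        p_value=p,
        se=se,
    )
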