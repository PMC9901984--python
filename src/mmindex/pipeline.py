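"""End-to-end pipeline: split, fit, score both indices, evaluate.

This is the library form of the ``run-all`` command: the 90/10
patient-level split, LR-table fit on the training side, MMI and DCI
scoring of the validation side, and the paired ROC/AUC comparison.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .charlson import DeyoConditionMap, dci_frame, score_cohort_dci
from .evaluate import AUCComparison, AUCResult, SplitSpec, auc, compare_auc
from .io import RunConfig
from .lr import LRTable, fit_lr_table, label_outcomes
from .scoring import build_histories, score_cohort, scores_frame

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    lr_table: LRTable
    mmi_scores: pd.DataFrame
    dci_scores: pd.DataFrame
    auc_mmi: AUCResult
    auc_dci: AUCResult
    comparison: AUCComparison
    n_train: int
    n_validation: int
    n_dead_validation: int

    def report(self) -> dict:
        """JSON-ready evaluation report."""

        def _auc(r: AUCResult) -> dict:
            return {
                "auc": r.auc,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_pos": r.n_pos,
                "n_neg": r.n_neg,
                "method": r.method,
            }

        c = self.comparison
        return {
            "auc_mmi": _auc(self.auc_mmi),
            "auc_dci": _auc(self.auc_dci),
            "comparison": {
                "delta_auc": c.delta,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "p_value": c.p_value,
                "relative_improvement": c.relative_improvement,
            },
            "n_train": self.n_train,
            "n_validation": self.n_validation,
            "n_dead_validation": self.n_dead_validation,
        }


def run_pipeline(
    diagnoses: pd.DataFrame,
    outcomes: pd.DataFrame,
    config: RunConfig,
    condition_map: DeyoConditionMap | None = None,
) -> PipelineResult:
    """Run the full train/validate comparison of MMI against DCI.

    The split is patient-level with ``config.train_fraction`` for
    training and ``config.seed`` for reproducibility; LR estimation sees
    only training patients, both indices are scored on validation
    patients only, and both are evaluated against the same 6-month
    mortality labels.
    """
    labels_all, _ = label_outcomes(outcomes, config.horizon_days)
    ids = outcomes["patient_id"].tolist()
    train_ids, valid_ids = _split(ids, labels_all, config)
    train_set, valid_set = set(train_ids), set(valid_ids)

    train_outcomes = outcomes[outcomes["patient_id"].isin(train_set)]
    valid_outcomes = outcomes[outcomes["patient_id"].isin(valid_set)]
    train_diag = diagnoses[diagnoses["patient_id"].isin(train_set)]
    valid_diag = diagnoses[diagnoses["patient_id"].isin(valid_set)]

    lr_table = fit_lr_table(
        train_diag,
        train_outcomes,
        horizon_days=config.horizon_days,
        min_cases=config.min_cases,
        lookback_days=config.lookback_days,
    )

    histories = build_histories(
        valid_diag, valid_outcomes, lookback_days=config.lookback_days
    )
    mmi = score_cohort(histories, lr_table, calibrated=config.calibrated)
    dci = score_cohort_dci(histories, condition_map)
    mmi_frame = scores_frame(mmi, explain=config.explain)
    dci_frm = dci_frame(dci, explain=config.explain)

    valid_labels, _ = label_outcomes(valid_outcomes, config.horizon_days)
    order = [h.patient_id for h in histories]
    y = valid_labels.reindex(order).to_numpy(dtype=bool)
    s_mmi = np.array([s.log_odds for s in mmi])
    s_dci = np.array([s.total for s in dci], dtype=float)

    auc_mmi = auc(s_mmi, y, method=config.ci_method, seed=config.seed)
    auc_dci = auc(s_dci, y, method=config.ci_method, seed=config.seed)
    comparison = compare_auc(s_mmi, s_dci, y)
    return PipelineResult(
        lr_table=lr_table,
        mmi_scores=mmi_frame,
        dci_scores=dci_frm,
        auc_mmi=auc_mmi,
        auc_dci=auc_dci,
        comparison=comparison,
        n_train=len(train_ids),
        n_validation=len(valid_ids),
        n_dead_validation=int(y.sum()),
    )


def _split(ids, labels: pd.Series, config: RunConfig) -> tuple[list, list]:
    from .evaluate import split_cohort

    lab = labels.reindex(ids).to_numpy(dtype=bool)
    return split_cohort(
        ids, SplitSpec(train_fraction=config.train_fraction, seed=config.seed), lab
    )
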