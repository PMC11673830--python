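"""Stage-classification metrics: accuracy, Cohen's kappa, macro F1,
sensitivity, specificity and one-vs-rest ROC AUC."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import cohen_kappa_score, confusion_matrix, roc_auc_score

from .seqcodec import ConsolidatedProbs, StagePredictions
from .types import N_STAGES, STAGES, StageLabels

__all__ = ["MetricsReport", "evaluate"]


@dataclass
class MetricsReport:
    acc: float
    kappa: float
    macro_f1: float
    macro_sens: float
    macro_spec: float
    per_class_f1: np.ndarray        # NaN where undefined
    confusion: np.ndarray           # (5, 5), rows = truth
    auc_per_class: np.ndarray       # NaN where undefined
    n_epochs: int = 0
    subject_id: str = ""
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"subject_id": self.subject_id, "n_epochs": self.n_epochs,
               "acc": self.acc, "kappa": self.kappa,
               "macro_f1": self.macro_f1, "macro_sens": self.macro_sens,
               "macro_spec": self.macro_spec}
        for i, s in enumerate(STAGES):
            row[f"f1_{s}"] = self.per_class_f1[i]
        row.update(self.extras)
        return row


def _as_codes(x) -> np.ndarray:
    if isinstance(x, StagePredictions):
        return np.asarray(x.stages, dtype=int)
    if isinstance(x, StageLabels):
        return np.asarray(x.codes(), dtype=int)
    return np.asarray(x, dtype=int)


def evaluate(pred, truth, scores: ConsolidatedProbs | np.ndarray | None = None,
             subject_id: str = "") -> MetricsReport:
    """Score predictions against a reference hypnogram.

    Per-class F1/sensitivity/specificity are one-vs-rest; the macro
    averages skip classes absent from both truth and prediction (their
    entries are NaN, with a warning).  AUC uses the L1-normalized
    consolidated scores when given.
    """
    y_pred = _as_codes(pred)
    y_true = _as_codes(truth)
    if y_pred.size != y_true.size:
        raise ValueError(f"{y_pred.size} predictions vs {y_true.size} labels")
    n = y_true.size
    labels = np.arange(N_STAGES)
    cm = confusion_matrix(y_true, y_pred, labels=labels)

    acc = float((y_pred == y_true).mean())
    kappa = float(cohen_kappa_score(y_true, y_pred, labels=labels)) \
        if np.unique(np.concatenate([y_true, y_pred])).size > 1 else 1.0

    f1 = np.full(N_STAGES, np.nan)
    sens = np.full(N_STAGES, np.nan)
    spec = np.full(N_STAGES, np.nan)
    for c in labels:
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = n - tp - fn - fp
        if tp + fn + fp == 0:
            continue                      # absent from truth and prediction
        f1[c] = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else np.nan
        sens[c] = tp / (tp + fn) if (tp + fn) else np.nan
        spec[c] = tn / (tn + fp) if (tn + fp) else np.nan
    if np.isnan(f1).any():
        absent = [STAGES[i] for i in np.flatnonzero(np.isnan(f1))]
        warnings.warn(f"classes absent from truth and prediction, excluded "
                      f"from macro averages: {absent}", RuntimeWarning)

    auc = np.full(N_STAGES, np.nan)
    if scores is not None:
        S = scores.scores if isinstance(scores, ConsolidatedProbs) \
            else np.asarray(scores, dtype=float)
        S = S / np.maximum(S.sum(axis=1, keepdims=True), 1e-12)
        for c in labels:
            pos = y_true == c
            if 0 < pos.sum() < n:
                auc[c] = roc_auc_score(pos.astype(int), S[:, c])

    return MetricsReport(
        acc=acc, kappa=kappa,
        macro_f1=float(np.nanmean(f1)),
        macro_sens=float(np.nanmean(sens)),
        macro_spec=float(np.nanmean(spec)),
        per_class_f1=f1, confusion=cm, auc_per_class=auc,
        n_epochs=n, subject_id=subject_id,
    )
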