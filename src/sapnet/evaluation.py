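"""Cross-validated benchmarking: ROC/AUC, confusion metrics, thresholds.

Conventions: the positive class is "deleterious" (label 1).  AUC uses the
rank-based (Mann-Whitney) estimator, so ties contribute 1/2.  MCC is the
2x2 determinant formula with the zero-marginal convention MCC = 0.
Cross-validation folds are stratified (the training classes of interest
are heavily imbalanced) and driven by a single seed recorded in every
report; calibration is refit inside each fold to avoid leakage, while the
network-derived T normalization is treated as unsupervised and fit once
globally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .io_formats import FormatError, ScoreVector
from .meta_score import CalibrationConfig, calibrate, finalize_score

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricsReport:
    """Confusion-table metrics (and AUC when score-based) of one evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    auc: float | None = None
    n_folds: int | None = None
    seed: int | None = None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "mcc": self.mcc,
            "auc": self.auc, "n_folds": self.n_folds, "seed": self.seed,
        }


def confusion_metrics(
    predictions: Sequence[int], labels: Sequence[int]
) -> MetricsReport:
    """Standard 2x2 metrics; MCC = 0 by convention when a marginal is zero."""
    pred = np.asarray(predictions, dtype=int)
    lab = np.asarray(labels, dtype=int)
    if pred.size == 0:
        raise FormatError("empty prediction set")
    if pred.shape != lab.shape:
        raise FormatError("predictions and labels differ in length")
    tp = int(np.sum((pred == 1) & (lab == 1)))
    fp = int(np.sum((pred == 1) & (lab == 0)))
    tn = int(np.sum((pred == 0) & (lab == 0)))
    fn = int(np.sum((pred == 0) & (lab == 1)))
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.info("zero marginal in confusion table; MCC set to 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy,
                         sensitivity=sensitivity, specificity=specificity,
                         mcc=float(mcc))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (rank-based estimator; ties count 1/2)."""
    lab = np.asarray(labels, dtype=int)
    if len(set(lab.tolist())) < 2:
        raise FormatError("AUC undefined: only one class present")
    return float(roc_auc_score(lab, np.asarray(scores, dtype=float)))


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """ROC curve points as a (fpr, tpr, threshold) frame for export."""
    fpr, tpr, thr = roc_curve(np.asarray(labels, int), np.asarray(scores, float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Observed score maximizing Youden's J = sensitivity + specificity - 1.

    The decision rule is ``score >= threshold``; ties in J break toward
    the higher threshold (favouring specificity).  A best J <= 0 (labels
    anti-separated or degenerate) is reported with a warning.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=int)
    if len(set(lab.tolist())) < 2:
        raise FormatError("threshold selection requires both classes")
    pos = s[lab == 1]
    neg = s[lab == 0]
    best_j, best_thr = -np.inf, None
    for thr in np.unique(s)[::-1]:          # descending: ties keep higher thr
        sens = np.mean(pos >= thr)
        spec = np.mean(neg < thr)
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_thr = j, float(thr)
    if best_j <= 0:
        warnings.warn(
            f"best Youden J = {best_j:.3f} <= 0: scores do not separate "
            "the classes in the expected direction",
            stacklevel=2,
        )
    return best_thr


@dataclass
class CvResult:
    """Per-fold and pooled held-out results of a k-fold cross-validation."""

    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    mean_over_folds: dict[str, float]
    held_out: pd.DataFrame          # label, meta, s, t, i, fold per SAP
    component_auc: dict[str, float]
    seed: int

    def to_dict(self) -> dict:
        return {
            "pooled": self.pooled.to_dict(),
            "mean_over_folds": self.mean_over_folds,
            "component_auc": self.component_auc,
            "fold_reports": [r.to_dict() for r in self.fold_reports],
            "seed": self.seed,
        }


def _binary_labels(scored: Sequence[ScoreVector]) -> np.ndarray:
    lab = []
    for sv in scored:
        if sv.sap.label == "deleterious":
            lab.append(1)
        elif sv.sap.label == "neutral":
            lab.append(0)
        else:
            raise FormatError(
                f"{sv.sap.protein_id}:{sv.sap.position}: unlabelled SAP in "
                "a labelled evaluation set"
            )
    return np.asarray(lab, dtype=int)


def kfold_cv(
    scored: Sequence[ScoreVector],
    k: int = 10,
    seed: int = 0,
    config: CalibrationConfig | None = None,
) -> CvResult:
    """Stratified k-fold cross-validation of the meta-score.

    ``scored`` must carry labels and raw component scores (S, T-norm, I);
    inside each fold the Condel weights and cutoffs are re-derived from
    the k-1 training folds only, then the held-out fold is meta-scored.
    The pooled report aggregates all held-out predictions; per-metric
    means over folds are reported alongside (the two aggregations answer
    slightly different questions and both are returned).
    """
    if k < 2:
        raise FormatError("k must be >= 2")
    labels = _binary_labels(scored)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if min(n_pos, n_neg) < k:
        raise FormatError(
            f"class counts ({n_pos} deleterious, {n_neg} neutral) are "
            f"smaller than k = {k}; use a smaller k"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scored = list(scored)
    fold_reports: list[MetricsReport] = []
    rows = []
    for fold, (train_idx, test_idx) in enumerate(
        splitter.split(np.zeros(len(scored)), labels)
    ):
        model = calibrate([scored[i] for i in train_idx], config=config)
        preds, labs = [], []
        for i in test_idx:
            sv = finalize_score(replace_shallow(scored[i]), model)
            preds.append(1 if sv.predicted_class == "deleterious" else 0)
            labs.append(labels[i])
            rows.append({
                "label": labels[i], "meta": sv.meta_score,
                "s": sv.s_score, "t": sv.t_norm,
                "i": sv.i_score, "fold": fold,
                "predicted": preds[-1],
            })
        fold_reports.append(replace(
            confusion_metrics(preds, labs), n_folds=k, seed=seed,
        ))
    held_out = pd.DataFrame(rows)
    pooled = replace(
        confusion_metrics(held_out["predicted"], held_out["label"]),
        auc=roc_auc(held_out["meta"], held_out["label"]),
        n_folds=k, seed=seed,
    )
    component_auc = {"meta": pooled.auc}
    for comp in ("s", "t", "i"):
        mask = held_out[comp].notna()
        sub = held_out[mask]
        if len(set(sub["label"])) == 2:
            # absent component scores count as 0 evidence over the full set
            full = held_out[comp].fillna(0.0)
            component_auc[comp] = roc_auc(full, held_out["label"])
    mean_over_folds = {
        m: float(np.mean([getattr(r, m) for r in fold_reports]))
        for m in ("accuracy", "sensitivity", "specificity", "mcc")
    }
    return CvResult(
        fold_reports=fold_reports,
        pooled=pooled,
        mean_over_folds=mean_over_folds,
        held_out=held_out,
        component_auc=component_auc,
        seed=seed,
    )


def replace_shallow(sv: ScoreVector) -> ScoreVector:
    """Fresh ScoreVector with the same components but no weights/meta."""
    return ScoreVector(
        sap=sv.sap, s_score=sv.s_score, t_raw=sv.t_raw,
        t_norm=sv.t_norm, i_score=sv.i_score,
    )
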