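"""Leave-one-out evaluation with proportion-based confusion metrics.

The confusion entries here are per-class *rates*, not raw counts: with N
patients (label +1) of which N1 are correctly classified, and M controls
(label -1) of which M1 are correct,

    TP = N1/N,  FN = (N - N1)/N,  TN = M1/M,  FP = (M - M1)/M,

so TP + FN = 1 and TN + FP = 1 always hold.  The six summary metrics are

    ACC = (TP + TN) / (TP + FN + TN + FP)          (= (TP + TN)/2)
    SN  = TP / (TP + FN)                           (= TP)
    SP  = TN / (TN + FP)                           (= TN)
    GM  = sqrt( TP * TN / ((TP + FN) * (TN + FP)) ) (= sqrt(TP * TN))
    DM  = 2 / ( (TP + FN)/TP + (TP + FP)/TP )
    F2M = 5 / ( 4*(TP + FN)/TP + (TP + FP)/TP )

with DM = F2M = 0 by continuity when TP = 0.  GM balances sensitivity and
specificity symmetrically; DM is a Dice-style harmonic mean of sensitivity
and precision, and F2M up-weights sensitivity — appropriate when missing a
patient costs more than a false alarm.

Evaluation is leave-one-out (LOO): every subject is held out exactly once.
Two protocols are provided because published pipelines are often ambiguous
about where feature selection sits relative to the folds:

``nested``
    t-test screening and RFE are re-run on each fold's training subjects
    only — no information from the held-out subject touches any selection
    statistic.  This is the leakage-free default.
``pooled``
    selection is computed once on all subjects and only the SVM is refit per
    fold.  Optimistically biased, provided to emulate the common (leaky)
    protocol; outputs are labeled with the mode.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .volumes import CohortMatrix
from .screening import ScreeningConfig, screen
from .rfe import RFEConfig, fit_linear_svm, select_features

__all__ = [
    "ConfusionProportions",
    "MetricSet",
    "FoldRecord",
    "EvaluationResult",
    "metrics_from_rates",
    "compute_metrics",
    "roc_auc",
    "loo_evaluate",
]


@dataclass(frozen=True)
class ConfusionProportions:
    """Per-class rate confusion entries (TP + FN = 1, TN + FP = 1)."""

    tp: float
    tn: float
    fn: float
    fp: float

    @classmethod
    def from_counts(cls, N: int, M: int, N1: int, M1: int) -> "ConfusionProportions":
        if N < 1 or M < 1:
            raise ValueError(f"class sizes must be >= 1, got N={N}, M={M}")
        if not (0 <= N1 <= N):
            raise ValueError(f"need 0 <= N1 <= N, got N1={N1}, N={N}")
        if not (0 <= M1 <= M):
            raise ValueError(f"need 0 <= M1 <= M, got M1={M1}, M={M}")
        return cls(tp=N1 / N, tn=M1 / M, fn=(N - N1) / N, fp=(M - M1) / M)

    @classmethod
    def from_rates(cls, sensitivity: float, specificity: float) -> "ConfusionProportions":
        if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
            raise ValueError("rates must lie in [0, 1]")
        return cls(tp=sensitivity, tn=specificity,
                   fn=1.0 - sensitivity, fp=1.0 - specificity)


@dataclass(frozen=True)
class MetricSet:
    """The six proportion-based metrics, plus AUC when scores are available."""

    acc: float
    sn: float
    sp: float
    gm: float
    dm: float
    f2m: float
    auc: float | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def metrics_from_rates(sensitivity: float, specificity: float) -> MetricSet:
    """Evaluate the metric formulas from a (sensitivity, specificity) pair.

    Because TP + FN = 1 and TN + FP = 1 by construction, this is the full
    information content of the proportion-based confusion table.
    """
    c = ConfusionProportions.from_rates(sensitivity, specificity)
    tp, tn, fn, fp = c.tp, c.tn, c.fn, c.fp
    acc = (tp + tn) / (tp + fn + tn + fp)
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    gm = np.sqrt(tp * tn / ((tp + fn) * (tn + fp)))
    if tp == 0:
        dm = f2m = 0.0
    else:
        dm = 2.0 / ((tp + fn) / tp + (tp + fp) / tp)
        f2m = 5.0 / (4.0 * (tp + fn) / tp + (tp + fp) / tp)
    return MetricSet(acc=float(acc), sn=float(sn), sp=float(sp),
                     gm=float(gm), dm=float(dm), f2m=float(f2m))


def compute_metrics(N: int, M: int, N1: int, M1: int) -> MetricSet:
    """Metrics from raw per-class counts (N, M class sizes; N1, M1 correct)."""
    c = ConfusionProportions.from_counts(N, M, N1, M1)
    return metrics_from_rates(c.tp, c.tn)


def roc_auc(scores, labels):
    """ROC points and AUC from decision scores (positive class +1).

    AUC equals the Mann-Whitney probability that a random positive scores
    above a random negative, with ties counted 1/2 — so all-equal scores give
    exactly 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thresholds = roc_curve(labels, scores, pos_label=1)
    auc = float(roc_auc_score(labels, scores))
    points = np.column_stack([fpr, tpr])
    return points, auc


@dataclass
class FoldRecord:
    fold: int
    y_true: int
    y_pred: int
    score: float
    n_selected: int
    failed: bool = False


@dataclass
class EvaluationResult:
    """Pooled LOO outcome: per-fold records, confusion rates, metrics, ROC."""

    folds: list[FoldRecord]
    proportions: ConfusionProportions
    metrics: MetricSet
    roc_points: np.ndarray
    mode: str
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(f) for f in self.folds])

    def to_json(self) -> str:
        payload = {
            "mode": self.mode,
            "config": self.config,
            "proportions": dataclasses.asdict(self.proportions),
            "metrics": self.metrics.as_dict(),
            "n_folds": len(self.folds),
            "n_failed_folds": int(sum(f.failed for f in self.folds)),
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def _majority_label(y: np.ndarray) -> int:
    # tie -> -1 (call the ambiguous case a control)
    return 1 if (y == 1).sum() > (y == -1).sum() else -1


def loo_evaluate(
    cohort: CohortMatrix,
    screening_config: ScreeningConfig | None = None,
    rfe_config: RFEConfig | None = None,
    mode: str = "nested",
) -> EvaluationResult:
    """Leave-one-out evaluation of the screen -> RFE -> linear-SVM pipeline.

    Parameters
    ----------
    cohort : full CohortMatrix (labels +1 patients / -1 controls)
    screening_config, rfe_config : stage parameters (C is rfe_config.C)
    mode : "nested" (selection inside each fold, leakage-free) or "pooled"
        (selection once on everyone, only the SVM refit per fold)

    A fold whose training screen yields no surviving voxel is recorded as a
    failure: the held-out subject gets the training majority-class label and
    a decision score of 0, and a warning is issued.
    """
    screening_config = screening_config or ScreeningConfig()
    rfe_config = rfe_config or RFEConfig()
    if mode not in ("nested", "pooled"):
        raise ValueError(f"mode must be 'nested' or 'pooled', got {mode!r}")
    y = cohort.y
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("need at least 2 subjects per class for LOO")

    pooled_columns = None
    if mode == "pooled":
        scr = screen(cohort, screening_config)
        if scr.n_selected == 0:
            raise ValueError("pooled-mode screening left no surviving voxels")
        _, _, prov = select_features(cohort, scr, rfe_config)
        pooled_columns = prov["retained_columns"]

    n = cohort.n_subjects
    records: list[FoldRecord] = []
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        sub = cohort.restrict_rows(train)
        if mode == "nested":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scr = screen(sub, screening_config)
            if scr.n_selected == 0:
                pred = _majority_label(sub.y)
                records.append(FoldRecord(i, int(y[i]), pred, 0.0, 0, failed=True))
                warnings.warn(f"fold {i}: empty surviving set, majority-class fallback",
                              stacklevel=2)
                scores[i], preds[i] = 0.0, pred
                continue
            _, _, prov = select_features(sub, scr, rfe_config)
            cols = prov["retained_columns"]
        else:
            cols = pooled_columns
        fit = fit_linear_svm(sub.X[:, cols], sub.y, C=rfe_config.C,
                             standardize=rfe_config.standardize)
        Xi = cohort.X[i, cols]
        if rfe_config.standardize:
            mu = sub.X[:, cols].mean(axis=0)
            sd = sub.X[:, cols].std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Xi = (Xi - mu) / sd
        score = float(np.asarray(Xi, dtype=float) @ fit.weights + fit.bias)
        pred = 1 if score > 0 else -1
        records.append(FoldRecord(i, int(y[i]), pred, score, int(len(cols))))
        scores[i], preds[i] = score, pred

    N = int((y == 1).sum())
    M = int((y == -1).sum())
    N1 = int(((y == 1) & (preds == 1)).sum())
    M1 = int(((y == -1) & (preds == -1)).sum())
    proportions = ConfusionProportions.from_counts(N, M, N1, M1)
    metrics = metrics_from_rates(proportions.tp, proportions.tn)
    roc_points, auc = roc_auc(scores, y)
    metrics = dataclasses.replace(metrics, auc=auc)
    return EvaluationResult(
        folds=records,
        proportions=proportions,
        metrics=metrics,
        roc_points=roc_points,
        mode=mode,
        config={
            "screening": dataclasses.asdict(screening_config),
            "rfe": dataclasses.asdict(rfe_config),
        },
    )
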