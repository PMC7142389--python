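"""Fine feature selection: linear-SVM weight ranking and recursive elimination.

A soft-margin linear SVM

    min_{w, b, zeta}  0.5 ||w||^2 + C * sum_i zeta_i
    s.t.  y_i (w^T x_i + b) >= 1 - zeta_i,  zeta_i >= 0

is fit on the current feature set; its primal weights are recovered from the
dual as ``w = sum_i alpha_i y_i x_i``, features are ranked by the squared
weight ``w_i^2``, and the lowest-ranked fraction of the *remaining* features
is removed each round.  Elimination stops when the retained set would drop
below ``ceil(retain_fraction * n)`` features; the final batch is truncated so
the retained count lands exactly on that size.

Squared-weight RFE is greedy: the ranking produced on the full set is not
re-used, every round refits on the shrunken set, which is what lets the
procedure discard redundant voxels a single fit would have shared weight
across.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
from sklearn.svm import SVC

from .volumes import CohortMatrix
from .screening import ScreeningResult

__all__ = [
    "SVMFit",
    "RFEConfig",
    "RoundLog",
    "RFERanking",
    "fit_linear_svm",
    "rfe_rank",
    "select_features",
]


@dataclass
class SVMFit:
    """A fitted soft-margin linear SVM.

    ``dual_coef`` holds ``alpha_i * y_i`` for the support vectors (row s of
    ``support_vectors``), so ``weights == dual_coef @ support_vectors`` is the
    dual-to-primal identity up to solver tolerance.
    """

    weights: np.ndarray
    bias: float
    dual_coef: np.ndarray
    support: np.ndarray
    support_vectors: np.ndarray
    C: float

    def decision(self, X) -> np.ndarray:
        """Decision values D(x) = w^T x + b."""
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        """Sign classification; a decision value of exactly 0 maps to -1."""
        return np.where(self.decision(X) > 0, 1, -1)


def fit_linear_svm(X, y, C: float = 1.0, standardize: bool = False) -> SVMFit:
    """Fit the soft-margin linear SVM at penalty ``C``.

    Deterministic for fixed input.  ``standardize`` z-scores the columns
    (statistics from this X only) before fitting; the returned weights then
    refer to the standardized features.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2D with at least one feature")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"need both classes present, got labels {classes}")
    if C <= 0:
        raise ValueError(f"C must be > 0, got {C}")
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    # sklearn orders classes ascending, so coef_ is the w for the +1 side.
    return SVMFit(
        weights=clf.coef_.ravel().astype(np.float64),
        bias=float(clf.intercept_[0]),
        dual_coef=clf.dual_coef_.ravel().astype(np.float64),
        support=clf.support_.copy(),
        support_vectors=clf.support_vectors_.astype(np.float64),
        C=float(C),
    )


@dataclass(frozen=True)
class RFEConfig:
    """Elimination schedule.

    C : SVM penalty (default 1.0)
    elim_fraction : fraction of the remaining features removed per round
        (default 0.05, i.e. 5% of the current set, at least 1 feature)
    retain_fraction : stop when ceil(retain_fraction * n) features remain
        (defaults used in practice: 0.40 for gray matter, 0.14 for white)
    standardize : z-score features (training statistics only) before each fit
    """

    C: float = 1.0
    elim_fraction: float = 0.05
    retain_fraction: float = 0.40
    standardize: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.elim_fraction < 1):
            raise ValueError(f"elim_fraction must be in (0, 1), got {self.elim_fraction}")
        if not (0 < self.retain_fraction <= 1):
            raise ValueError(f"retain_fraction must be in (0, 1], got {self.retain_fraction}")
        if self.C <= 0:
            raise ValueError(f"C must be > 0, got {self.C}")


@dataclass
class RoundLog:
    round: int
    removed: np.ndarray     # feature indices removed this round, worst first
    criterion: np.ndarray   # their squared weights
    n_remaining: int        # features left after the removal


@dataclass
class RFERanking:
    """Outcome of recursive elimination over ``n_features`` input columns.

    ``rank`` is 1 for the most important feature (eliminated last or retained
    with the largest final squared weight); ties in the criterion are broken
    by ascending column index.  ``retained`` is the surviving index set in
    ascending order, of size exactly ``ceil(retain_fraction * n_features)``.
    """

    rank: np.ndarray
    retained: np.ndarray
    rounds: list[RoundLog] = field(default_factory=list)
    n_features: int = 0


def elimination_schedule(n: int, elim_fraction: float, retain_fraction: float) -> list[int]:
    """Per-round removal counts for ``n`` features (the last one truncated)."""
    target = ceil(retain_fraction * n)
    counts = []
    remaining = n
    while remaining > target:
        k = min(max(1, ceil(elim_fraction * remaining)), remaining - target)
        counts.append(k)
        remaining -= k
    return counts


def rfe_rank(X, y, config: RFEConfig | None = None) -> RFERanking:
    """Recursively eliminate features by squared linear-SVM weight.

    Each round refits the SVM on the remaining features, ranks them by
    ``w_i^2`` and removes the ``ceil(elim_fraction * |F|)`` weakest (at least
    one, truncated so the retained count lands exactly on
    ``ceil(retain_fraction * n)``).
    """
    config = config or RFEConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2D with at least one feature")
    n = X.shape[1]
    target = ceil(config.retain_fraction * n)

    remaining = np.arange(n)
    rounds: list[RoundLog] = []
    eliminated: list[int] = []  # order of elimination, first-removed first
    rnd = 0
    while remaining.size > target:
        rnd += 1
        fit = fit_linear_svm(
            X[:, remaining], y, C=config.C, standardize=config.standardize
        )
        crit = fit.weights**2
        k = min(max(1, ceil(config.elim_fraction * remaining.size)), remaining.size - target)
        order = np.argsort(crit, kind="stable")  # ascending criterion, ties by index
        drop_local = order[:k]
        rounds.append(
            RoundLog(
                round=rnd,
                removed=remaining[drop_local].copy(),
                criterion=crit[drop_local].copy(),
                n_remaining=remaining.size - k,
            )
        )
        eliminated.extend(int(f) for f in remaining[drop_local])
        keep = np.ones(remaining.size, dtype=bool)
        keep[drop_local] = False
        remaining = remaining[keep]

    # Rank retained features by the final fit's criterion (descending).
    if remaining.size > 1:
        final = fit_linear_svm(X[:, remaining], y, C=config.C,
                               standardize=config.standardize)
        final_order = np.argsort(-(final.weights**2), kind="stable")
        retained_by_rank = remaining[final_order]
    else:
        retained_by_rank = remaining

    rank = np.empty(n, dtype=np.intp)
    rank[retained_by_rank] = np.arange(1, remaining.size + 1)
    # Later-eliminated features are more important than earlier-eliminated.
    for pos, feat in enumerate(reversed(eliminated)):
        rank[feat] = remaining.size + 1 + pos
    return RFERanking(
        rank=rank,
        retained=np.sort(remaining),
        rounds=rounds,
        n_features=n,
    )


def select_features(
    cohort: CohortMatrix,
    screening_result: ScreeningResult,
    config: RFEConfig | None = None,
):
    """Apply RFE to the screening-surviving columns of a cohort.

    Returns ``(reduced_cohort, ranking, provenance)`` where the reduced
    cohort keeps ``ceil(retain_fraction * n_surviving)`` columns, ``ranking``
    indexes the *surviving* columns, and ``provenance["retained_columns"]``
    gives the retained indices in the original cohort's column space.
    """
    config = config or RFEConfig()
    surviving = np.asarray(screening_result.selected_columns)
    if surviving.size == 0:
        raise ValueError(
            "screening left no surviving voxels; relax alpha or min_cluster "
            "before running RFE"
        )
    ranking = rfe_rank(cohort.X[:, surviving], cohort.y, config)
    retained_columns = surviving[ranking.retained]
    reduced = cohort.restrict_columns(retained_columns)
    provenance = {
        "screening": dict(screening_result.metadata),
        "rfe": {
            "C": config.C,
            "elim_fraction": config.elim_fraction,
            "retain_fraction": config.retain_fraction,
            "standardize": config.standardize,
        },
        "n_surviving": int(surviving.size),
        "n_retained": int(retained_columns.size),
        "retained_columns": retained_columns,
    }
    return reduced, ranking, provenance
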