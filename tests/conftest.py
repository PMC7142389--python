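"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from vbmlearn import BlobSpec, CohortMatrix, CohortSpec, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def matrix_cohort(X, y) -> CohortMatrix:
    """Wrap a plain feature matrix as a CohortMatrix on an (n, 1, 1) grid."""
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    idx = np.stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)], axis=1)
    return CohortMatrix(X, np.asarray(y), idx, (n, 1, 1), np.eye(4))


@pytest.fixture
def blob_cohort_spec():
    """Strong planted blob at desk scale: 10+10 subjects on a 12-cube."""
    return CohortSpec(
        grid_shape=(12, 12, 12),
        n_group1=10,
        n_group2=10,
        blobs=(BlobSpec((6, 6, 6), 2.5, 0.6),),
        subject_sd=0.02,
        voxel_sd=0.1,
        fwhm_mm=3.0,
        voxel_size_mm=2.0,
        seed=1,
    )


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive; never reuse package code)
# ---------------------------------------------------------------------------

def flood_fill_components(mask: np.ndarray, connectivity: int):
    """Brute-force BFS connected components of a 3D boolean array."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = []
        while queue:
            v = queue.pop()
            comp.append(v)
            for off in offsets:
                w = tuple(a + d for a, d in zip(v, off))
                if all(0 <= c < n for c, n in zip(w, mask.shape)) and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(frozenset(comp))
    return comps


def pair_count_auc(scores, labels) -> float:
    """AUC by exhaustive positive/negative pair counting, ties worth 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (pos.size * neg.size)


def brute_force_rfe_order(X, y, C=1.0):
    """One-at-a-time elimination: refit, drop argmin w_i^2 (ties: low index)."""
    from sklearn.svm import SVC

    X = np.asarray(X, float)
    remaining = list(range(X.shape[1]))
    order = []
    while len(remaining) > 1:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[:, remaining], y)
        crit = clf.coef_.ravel() ** 2
        worst = int(np.argmin(crit))  # argmin takes the lowest index on ties
        order.append(remaining.pop(worst))
    order.append(remaining[0])
    return order  # first-removed ... last-removed
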