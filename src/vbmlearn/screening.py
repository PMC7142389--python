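"""Coarse feature selection: voxelwise two-sample t-tests plus cluster extent.

The screen computes, at every voxel, the pooled-variance two-sample t
statistic

    T = (mean1 - mean2) / sqrt( ((N1-1)*S1^2 + (N2-1)*S2^2) / (N1+N2-2)
                                * (1/N1 + 1/N2) )

with df = N1 + N2 - 2, thresholds the two-sided p-value, and keeps only
supra-threshold voxels that belong to a 3D connected cluster of at least
``min_cluster`` voxels.  The larger |T|, the more discriminative the voxel;
the extent filter discards isolated significances, which is how VBM studies
conventionally separate signal from salt-and-pepper false positives.

No multiple-testing correction is applied by default (raw p plus extent is
the convention this pipeline follows); an optional Bonferroni flag exists
for users who want it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .volumes import CohortMatrix, Volume3D

__all__ = [
    "ScreeningConfig",
    "Cluster",
    "ScreeningResult",
    "ttest_voxelwise",
    "connected_components",
    "screen",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class ScreeningConfig:
    """Screening parameters.

    alpha : two-sided p threshold (default 0.05)
    min_cluster : minimum surviving-cluster voxel count (default 50)
    connectivity : 3D neighborhood, one of 6 (faces), 18 (+edges), 26 (+corners)
    bonferroni : divide alpha by the number of tested voxels first
    """

    alpha: float = 0.05
    min_cluster: int = 50
    connectivity: int = 26
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_cluster < 1:
            raise ValueError(f"min_cluster must be >= 1, got {self.min_cluster}")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError(
                f"connectivity must be one of 6, 18, 26, got {self.connectivity}"
            )


@dataclass
class Cluster:
    """A maximal connected set of voxels."""

    indices: np.ndarray  # (size, 3) voxel coordinates
    size: int


@dataclass
class ScreeningResult:
    """Per-voxel statistics plus the surviving voxel set.

    ``t``/``p``/``zero_variance`` are per cohort column; ``t_map``/``p_map``
    scatter them onto the grid (0 and 1 outside the mask respectively).
    ``selected_columns`` indexes the cohort's columns that survived.
    """

    t: np.ndarray
    p: np.ndarray
    zero_variance: np.ndarray
    t_map: Volume3D
    p_map: Volume3D
    surviving: Volume3D
    clusters: list[Cluster]
    selected_columns: np.ndarray
    config: ScreeningConfig
    metadata: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return int(self.selected_columns.size)


def ttest_voxelwise(cohort: CohortMatrix):
    """Pooled two-sample t statistic and two-sided p at every column.

    Returns ``(t, p, zero_variance)``.  At a zero-pooled-variance voxel, T is
    0 (p = 1) when the group means agree and +/-inf (p = 0) otherwise; such
    voxels are flagged in the returned boolean array.
    """
    y = cohort.y
    g1 = cohort.X[y == 1]
    g2 = cohort.X[y == -1]
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need >= 2 subjects, got {n1} and {n2}")
    df = n1 + n2 - 2
    m1 = g1.mean(axis=0)
    m2 = g2.mean(axis=0)
    s1 = g1.var(axis=0, ddof=1)
    s2 = g2.var(axis=0, ddof=1)
    pooled = ((n1 - 1) * s1 + (n2 - 1) * s2) / df
    denom = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    zero_var = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t[zero_var & (diff == 0)] = 0.0
    t[zero_var & (diff > 0)] = np.inf
    t[zero_var & (diff < 0)] = -np.inf
    p = np.empty_like(t)
    finite = np.isfinite(t)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), df)
    p[~finite] = 0.0
    return t, p, zero_var


def connected_components(mask: Volume3D, connectivity: int = 26) -> list[Cluster]:
    """Partition a binary volume into maximal connected clusters.

    Clusters are ordered by their minimum C-order linear voxel index, so the
    output is deterministic.  An empty mask gives an empty list.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26, got {connectivity}")
    data = np.asarray(mask.data) != 0
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(data, structure=structure)
    groups = ndimage.value_indices(labels, ignore_value=0)
    clusters = []
    for lab, idx in groups.items():
        coords = np.stack(idx, axis=1)
        clusters.append(Cluster(indices=coords, size=coords.shape[0]))
    clusters.sort(
        key=lambda c: int(np.ravel_multi_index(tuple(c.indices.T), data.shape).min())
    )
    return clusters


def screen(cohort: CohortMatrix, config: ScreeningConfig | None = None) -> ScreeningResult:
    """Run the coarse screen: t-test, p threshold, cluster-extent filter.

    The surviving set is the union of supra-threshold clusters of size >=
    ``min_cluster``.  An empty surviving set produces a warning (not an
    error) and an empty result.
    """
    config = config or ScreeningConfig()
    t, p, zero_var = ttest_voxelwise(cohort)
    alpha = config.alpha / cohort.n_voxels if config.bonferroni else config.alpha

    supra = p < alpha
    supra_vol = cohort.scatter(supra.astype(np.float64))
    supra_vol.data = supra_vol.data != 0
    all_clusters = connected_components(
        Volume3D(supra_vol.data.astype(np.uint8), cohort.affine), config.connectivity
    )
    clusters = [c for c in all_clusters if c.size >= config.min_cluster]

    surviving = np.zeros(cohort.shape, dtype=np.uint8)
    for c in clusters:
        i, j, k = c.indices.T
        surviving[i, j, k] = 1
    i, j, k = cohort.mask_indices.T
    selected = np.flatnonzero(surviving[i, j, k])

    if selected.size == 0:
        warnings.warn(
            "screening produced an empty surviving set "
            f"(alpha={config.alpha}, min_cluster={config.min_cluster})",
            stacklevel=2,
        )

    result = ScreeningResult(
        t=t,
        p=p,
        zero_variance=zero_var,
        t_map=cohort.scatter(np.where(np.isfinite(t), t, 0.0)),
        p_map=cohort.scatter(p, fill=1.0),
        surviving=Volume3D(surviving, cohort.affine.copy()),
        clusters=clusters,
        selected_columns=selected,
        config=config,
        metadata={
            "alpha": config.alpha,
            "effective_alpha": alpha,
            "min_cluster": config.min_cluster,
            "connectivity": config.connectivity,
            "n_voxels": cohort.n_voxels,
            "n_supra": int(supra.sum()),
            "n_selected": int(selected.size),
        },
    )
    return result
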