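"""Biomarker region reports: clusters of retained voxels with atlas labels.

Mirrors how VBM studies table their findings: each connected cluster of the
retained mask (at or above a size threshold) is reported with its voxel
count, the world-space coordinate of its peak |T| voxel, and — when an
integer-labeled atlas on the same grid is supplied — the majority atlas
label plus the full per-label voxel histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import Volume3D, voxel_to_world
from .screening import connected_components

__all__ = ["RegionRecord", "report_regions", "regions_to_frame"]

UNASSIGNED = "unassigned"


@dataclass
class RegionRecord:
    cluster_id: int
    size: int
    peak_voxel: tuple[int, int, int]
    peak_world: tuple[float, float, float]
    peak_t: float
    majority_label: object  # int atlas id, or "unassigned"
    label_counts: dict = field(default_factory=dict)
    p_threshold: float | None = None


def report_regions(
    retained: Volume3D,
    t_map: Volume3D,
    atlas: Volume3D | None = None,
    min_cluster: int = 50,
    connectivity: int = 26,
    p_threshold: float | None = None,
) -> list[RegionRecord]:
    """Cluster the retained mask and describe each cluster.

    Clusters smaller than ``min_cluster`` are dropped; records come back in
    descending size order.  The peak is the voxel with the largest |T| in the
    cluster, ties broken by lowest C-order linear index; its coordinate is
    reported in world (mm) space through the mask's affine.
    """
    if t_map.shape != retained.shape:
        raise ValueError(f"t_map shape {t_map.shape} != mask shape {retained.shape}")
    if atlas is not None:
        if atlas.shape != retained.shape:
            raise ValueError(f"atlas shape {atlas.shape} != mask shape {retained.shape}")
        if not np.allclose(atlas.affine, retained.affine):
            raise ValueError("atlas affine differs from the retained mask's")

    clusters = [
        c for c in connected_components(retained, connectivity)
        if c.size >= min_cluster
    ]
    tdata = np.asarray(t_map.data)
    adata = None if atlas is None else np.asarray(atlas.data)

    records = []
    for c in clusters:
        i, j, k = c.indices.T
        tvals = np.abs(tdata[i, j, k])
        lin = np.ravel_multi_index((i, j, k), retained.shape)
        # max |T|, ties -> lowest linear index: sort keys (−|T|, lin)
        best = np.lexsort((lin, -tvals))[0]
        peak = tuple(int(v) for v in c.indices[best])
        world = tuple(float(v) for v in voxel_to_world(np.array(peak), retained.affine))
        if adata is None:
            majority: object = UNASSIGNED
            counts: dict = {}
        else:
            labs, cnts = np.unique(adata[i, j, k].astype(np.int64), return_counts=True)
            counts = {int(l): int(n) for l, n in zip(labs, cnts)}
            majority = int(labs[np.argmax(cnts)])
        records.append(
            RegionRecord(
                cluster_id=0,  # assigned after the size sort
                size=c.size,
                peak_voxel=peak,
                peak_world=world,
                peak_t=float(tdata[peak]),
                majority_label=majority,
                label_counts=counts,
                p_threshold=p_threshold,
            )
        )
    records.sort(key=lambda r: -r.size)
    for n, r in enumerate(records, start=1):
        r.cluster_id = n
    return records


def regions_to_frame(records: list[RegionRecord]) -> pd.DataFrame:
    """Tabulate a region report (one row per cluster, TSV-ready)."""
    rows = []
    for r in records:
        rows.append(
            {
                "cluster_id": r.cluster_id,
                "majority_label": r.majority_label,
                "size": r.size,
                "peak_x_mm": r.peak_world[0],
                "peak_y_mm": r.peak_world[1],
                "peak_z_mm": r.peak_world[2],
                "peak_t": r.peak_t,
                "p_threshold": r.p_threshold,
                "label_counts": ";".join(
                    f"{l}:{n}" for l, n in sorted(r.label_counts.items())
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "majority_label", "size",
            "peak_x_mm", "peak_y_mm", "peak_z_mm",
            "peak_t", "p_threshold", "label_counts",
        ],
    )
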