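"""Synthetic two-group cohorts of smoothed tissue-map volumes.

The generator emulates what voxel-based morphometry preprocessing hands to a
classifier: per-subject modulated tissue maps that are spatially smooth, share
a common baseline, and differ between groups in a few localized regions.  A
cohort is a baseline intensity plus a per-subject global offset (between-
subject variability), white voxel noise, spherical "blob" effects added to
group 1 before smoothing, and finally Gaussian smoothing at a stated FWHM —
so planted regions have the smooth boundaries real VBM effects do.

Everything is driven by a single integer seed and is bit-reproducible.  The
ground truth (which voxels carry a planted effect) is returned alongside the
data so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import Volume3D, gaussian_smooth, to_matrix, write_volume, read_volume

__all__ = [
    "BlobSpec",
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "make_synthetic_atlas",
    "write_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class BlobSpec:
    """A spherical region of group-mean difference.

    Parameters
    ----------
    center : (i, j, k) voxel-index triple
    radius : Euclidean radius in voxels; the blob is every grid voxel v with
        ``||v - center||_2 <= radius``
    effect : signed mean shift added to group-1 subjects inside the blob
        (tissue-intensity units, i.e. unit-free)
    """

    center: tuple[int, int, int]
    radius: float
    effect: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(int(c) for c in self.center))
        object.__setattr__(self, "radius", float(self.radius))
        object.__setattr__(self, "effect", float(self.effect))

    def validate(self, grid_shape: tuple[int, int, int]) -> None:
        if self.radius <= 0:
            raise ValueError(f"BlobSpec.radius must be > 0, got {self.radius}")
        if len(self.center) != 3:
            raise ValueError("BlobSpec.center must be an (i, j, k) triple")
        for ax, (c, n) in enumerate(zip(self.center, grid_shape)):
            if not (0 <= c < n):
                raise ValueError(
                    f"BlobSpec.center axis {ax} value {c} outside grid of size {n}"
                )

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean volume of the blob's voxel set (always nonempty)."""
        grids = np.indices(grid_shape, dtype=np.float64)
        d2 = sum((g - c) ** 2 for g, c in zip(grids, self.center))
        return d2 <= self.radius**2


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic two-group cohort.

    Defaults mirror the study scale this package targets: 34 + 34 subjects,
    6 mm FWHM smoothing on a small grid for desk-scale runtime.  ``baseline``
    is unit-free (modulated tissue maps carry no canonical intensity scale).
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_group1: int = 34
    n_group2: int = 34
    baseline: float = 1.0
    subject_sd: float = 0.05
    voxel_sd: float = 0.1
    blobs: tuple[BlobSpec, ...] = ()
    fwhm_mm: float = 6.0
    voxel_size_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(
            self,
            "blobs",
            tuple(b if isinstance(b, BlobSpec) else BlobSpec(**b) for b in self.blobs),
        )
        self.validate()

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 1 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive ints, got {self.grid_shape}")
        if self.n_group1 < 2:
            raise ValueError(f"n_group1 must be >= 2 (t-test needs df >= 1), got {self.n_group1}")
        if self.n_group2 < 2:
            raise ValueError(f"n_group2 must be >= 2 (t-test needs df >= 1), got {self.n_group2}")
        if self.subject_sd < 0:
            raise ValueError(f"subject_sd must be >= 0, got {self.subject_sd}")
        if self.voxel_sd < 0:
            raise ValueError(f"voxel_sd must be >= 0, got {self.voxel_sd}")
        if self.fwhm_mm < 0:
            raise ValueError(f"fwhm_mm must be >= 0, got {self.fwhm_mm}")
        if self.voxel_size_mm <= 0:
            raise ValueError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")
        for blob in self.blobs:
            blob.validate(self.grid_shape)

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size_mm] * 3 + [1.0])

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        return cls(**json.loads(text))


@dataclass
class GroundTruth:
    """Where the planted effects are.

    ``effect_mask`` is nonzero exactly on the union of blob voxel sets;
    ``blob_voxels`` lists each blob's (n, 3) voxel-index array.
    """

    effect_mask: Volume3D
    blob_voxels: list[np.ndarray] = field(default_factory=list)

    def effect_columns(self, cohort) -> np.ndarray:
        """Column indices of a CohortMatrix that fall inside any blob."""
        mask = np.asarray(self.effect_mask.data) != 0
        i, j, k = cohort.mask_indices.T
        return np.flatnonzero(mask[i, j, k])


def generate_cohort(spec: CohortSpec):
    """Generate a seeded synthetic cohort.

    Returns
    -------
    volumes : list of Volume3D, group 1 first then group 2
    labels : array of +1 (group 1) / -1 (group 2)
    truth : GroundTruth

    Each volume is ``baseline + subject_offset + voxel noise`` with blob
    effects added to group-1 subjects before smoothing, then smoothed at
    ``fwhm_mm``.  Identical spec (including seed) gives bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    n_total = spec.n_group1 + spec.n_group2

    effect = np.zeros(shape, dtype=np.float64)
    blob_voxels: list[np.ndarray] = []
    union = np.zeros(shape, dtype=bool)
    for blob in spec.blobs:
        m = blob.mask(shape)
        effect[m] += blob.effect
        blob_voxels.append(np.argwhere(m))
        union |= m

    offsets = rng.normal(0.0, spec.subject_sd, size=n_total)
    volumes: list[Volume3D] = []
    for s in range(n_total):
        data = np.full(shape, spec.baseline + offsets[s], dtype=np.float64)
        if spec.voxel_sd > 0:
            data += rng.normal(0.0, spec.voxel_sd, size=shape)
        if s < spec.n_group1:
            data += effect
        volumes.append(gaussian_smooth(Volume3D(data, spec.affine), spec.fwhm_mm))

    labels = np.concatenate(
        [np.ones(spec.n_group1, dtype=int), -np.ones(spec.n_group2, dtype=int)]
    )
    truth = GroundTruth(
        Volume3D(union.astype(np.uint8), spec.affine), blob_voxels
    )
    return volumes, labels, truth


def _bisect(boxes, counts):
    """Recursively split boxes (index slabs) until each holds one region."""
    out = []
    for box, n in zip(boxes, counts):
        if n == 1:
            out.append(box)
            continue
        n1 = n // 2
        n2 = n - n1
        (lo, hi) = box[(ax := int(np.argmax([b[1] - b[0] for b in box])))]
        extent = hi - lo
        # proportional split, adjusted so each side can host its regions
        s = int(round(extent * n1 / n))
        s = min(max(s, 1), extent - 1)
        other = 1
        for a, (l, h) in enumerate(box):
            if a != ax:
                other *= h - l
        while s * other < n1 and s < extent - 1:
            s += 1
        while (extent - s) * other < n2 and s > 1:
            s -= 1
        left = list(box)
        right = list(box)
        left[ax] = (lo, lo + s)
        right[ax] = (lo + s, hi)
        out.extend(_bisect([tuple(left), tuple(right)], [n1, n2]))
    return out


def make_synthetic_atlas(grid_shape, n_regions: int, seed: int = 0) -> Volume3D:
    """Partition a grid into ``n_regions`` labeled rectangular parcels.

    Stands in for an anatomical atlas in tests and demos.  The geometry comes
    from deterministic recursive coordinate bisection (the longest axis of
    each box is split proportionally), so every region is a nonempty box and
    every voxel carries exactly one label in ``1..n_regions``; the seed only
    permutes which box gets which label.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if n_regions < 1:
        raise ValueError(f"n_regions must be >= 1, got {n_regions}")
    total = int(np.prod(grid_shape))
    if n_regions > total:
        raise ValueError(
            f"n_regions={n_regions} exceeds the voxel count {total} of {grid_shape}"
        )
    root = tuple((0, n) for n in grid_shape)
    boxes = _bisect([root], [n_regions])
    labels = np.random.default_rng(seed).permutation(n_regions) + 1
    out = np.zeros(grid_shape, dtype=np.int32)
    for box, lab in zip(boxes, labels):
        sl = tuple(slice(lo, hi) for lo, hi in box)
        out[sl] = lab
    return Volume3D(out, np.eye(4))


def write_cohort(volumes, labels, out_dir, truth: GroundTruth | None = None,
                 spec: CohortSpec | None = None) -> Path:
    """Write a cohort as per-subject NIfTI files plus a phenotype TSV.

    The TSV has columns subject_id, path, group; ground truth (if given) goes
    to ``ground_truth.nii.gz`` and the spec to ``cohort_spec.json``.  Returns
    the phenotype path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s, (vol, lab) in enumerate(zip(volumes, labels)):
        name = f"sub-{s:03d}.nii.gz"
        write_volume(vol, out_dir / name)
        rows.append({"subject_id": f"sub-{s:03d}", "path": name, "group": int(lab)})
    pheno = out_dir / "phenotype.tsv"
    pd.DataFrame(rows).to_csv(pheno, sep="\t", index=False)
    if truth is not None:
        write_volume(truth.effect_mask, out_dir / "ground_truth.nii.gz")
    if spec is not None:
        (out_dir / "cohort_spec.json").write_text(spec.to_json() + "\n")
    return pheno


def load_cohort(phenotype_path, mask=None):
    """Read a phenotype TSV (subject_id, path, group) back into a CohortMatrix.

    Relative volume paths are resolved against the TSV's directory.
    """
    phenotype_path = Path(phenotype_path)
    table = pd.read_csv(phenotype_path, sep="\t")
    for col in ("subject_id", "path", "group"):
        if col not in table.columns:
            raise ValueError(f"phenotype file missing column {col!r}")
    base = phenotype_path.parent
    volumes = []
    for p in table["path"]:
        p = Path(p)
        volumes.append(read_volume(p if p.is_absolute() else base / p))
    labels = table["group"].to_numpy(dtype=int)
    mask_vol = read_volume(mask) if isinstance(mask, (str, os.PathLike)) else mask
    return to_matrix(volumes, labels, mask_vol if mask_vol is not None else "all")
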