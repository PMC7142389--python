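"""Volumes and cohort matrices.

3D scalar grids with a NIfTI-style affine, Gaussian smoothing at a stated
FWHM, and the subjects-by-voxels matrix view used by every downstream stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "CohortMatrix",
    "read_volume",
    "write_volume",
    "gaussian_smooth",
    "to_matrix",
    "voxel_to_world",
    "world_to_voxel",
    "FWHM_TO_SIGMA",
]

#: sigma = FWHM / (2 * sqrt(2 * ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Volume3D:
    """A 3D scalar grid plus a 4x4 voxel-to-world (mm) affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D.data must be 3D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("Volume3D.affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("Volume3D.affine must be invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.affine.copy())


def read_volume(path: str | os.PathLike) -> Volume3D:
    """Read a NIfTI-1 volume from ``path``."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise IOError(f"cannot read NIfTI volume from {path!r}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise IOError(f"{path!r} is not a 3D volume (shape {data.shape})")
    return Volume3D(data, np.asarray(img.affine, dtype=float))


def write_volume(vol: Volume3D, path: str | os.PathLike) -> None:
    """Write ``vol`` to ``path`` as NIfTI-1 (float64)."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    nib.save(img, str(path))


def gaussian_smooth(vol: Volume3D, fwhm_mm: float, mode: str = "reflect") -> Volume3D:
    """Smooth with an isotropic-in-mm Gaussian kernel of the given FWHM.

    The kernel standard deviation is ``fwhm_mm / (2 * sqrt(2 * ln 2))`` mm,
    converted to voxels per axis; anisotropic voxels simply get per-axis
    sigmas.  ``fwhm_mm = 0`` returns a copy of the input unchanged.
    Boundary handling defaults to "reflect".
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return vol.copy()
    from scipy import ndimage

    sigma_mm = fwhm_mm * FWHM_TO_SIGMA
    sigma_vox = sigma_mm / vol.voxel_sizes()
    out = ndimage.gaussian_filter(
        np.asarray(vol.data, dtype=np.float64), sigma=sigma_vox, mode=mode
    )
    return Volume3D(out, vol.affine.copy())


def voxel_to_world(index, affine: np.ndarray) -> np.ndarray:
    """Map voxel indices to world (mm) coordinates through the affine.

    ``index`` may be one triple or an (n, 3) array.
    """
    idx = np.atleast_2d(np.asarray(index, dtype=float))
    world = idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    return world[0] if np.asarray(index).ndim == 1 else world


def world_to_voxel(coord, affine: np.ndarray) -> np.ndarray:
    """Inverse of :func:`voxel_to_world` (continuous voxel coordinates)."""
    inv = np.linalg.inv(np.asarray(affine))
    pts = np.atleast_2d(np.asarray(coord, dtype=float))
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    return vox[0] if np.asarray(coord).ndim == 1 else vox


@dataclass
class CohortMatrix:
    """Subjects x voxels feature matrix extracted under a mask.

    Columns are a fixed deterministic linearization of the mask: ascending
    (i, j, k) lexicographic order, so rankings and reports are reproducible.

    Attributes
    ----------
    X : (n_subjects, n_voxels) float array
    y : (n_subjects,) labels in {+1, -1}
    mask_indices : (n_voxels, 3) int array, grid coordinate of each column
    shape : grid shape the columns live on
    affine : shared voxel-to-world transform
    """

    X: np.ndarray
    y: np.ndarray
    mask_indices: np.ndarray
    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        self.mask_indices = np.asarray(self.mask_indices, dtype=np.intp)
        if self.X.ndim != 2:
            raise ValueError("X must be 2D (subjects x voxels)")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("rows of X must match length of y")
        if self.X.shape[1] != self.mask_indices.shape[0]:
            raise ValueError("columns of X must match mask_indices")
        if not np.all(np.isin(self.y, (-1, 1))):
            raise ValueError("labels must be +1 or -1")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def restrict_columns(self, cols) -> "CohortMatrix":
        cols = np.asarray(cols, dtype=np.intp)
        return replace(
            self, X=self.X[:, cols], mask_indices=self.mask_indices[cols]
        )

    def restrict_rows(self, rows) -> "CohortMatrix":
        rows = np.asarray(rows)
        return replace(self, X=self.X[rows], y=self.y[rows])

    def scatter(self, values, fill: float = 0.0) -> Volume3D:
        """Scatter one per-column vector back onto the grid."""
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise ValueError("values must have one entry per column")
        out = np.full(self.shape, fill, dtype=np.float64)
        i, j, k = self.mask_indices.T
        out[i, j, k] = values
        return Volume3D(out, self.affine.copy())

    def column_world_coords(self) -> np.ndarray:
        """World (mm) coordinate of every column's voxel."""
        return voxel_to_world(self.mask_indices, self.affine)

    def linear_indices(self) -> np.ndarray:
        """C-order linear grid index of every column."""
        return np.ravel_multi_index(tuple(self.mask_indices.T), self.shape)


def to_matrix(volumes, labels, mask: Volume3D | str | None = "all") -> CohortMatrix:
    """Stack per-subject volumes into a :class:`CohortMatrix` under a mask.

    Parameters
    ----------
    volumes : sequence of Volume3D sharing shape and affine
    labels : sequence of +1 / -1 group labels, one per subject
    mask : binary Volume3D, or "all"/None for every voxel

    Raises
    ------
    ValueError
        If any volume's shape or affine disagrees with the first subject's;
        the error names the offending subject index.
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("need at least one volume")
    labels = np.asarray(labels)
    if labels.shape[0] != len(volumes):
        raise ValueError("one label per volume required")
    ref = volumes[0]
    for s, vol in enumerate(volumes):
        if vol.shape != ref.shape:
            raise ValueError(f"subject {s}: shape {vol.shape} != {ref.shape}")
        if not np.allclose(vol.affine, ref.affine):
            raise ValueError(f"subject {s}: affine mismatch with subject 0")

    if mask is None or (isinstance(mask, str) and mask == "all"):
        mask_bool = np.ones(ref.shape, dtype=bool)
    else:
        if mask.shape != ref.shape:
            raise ValueError(f"mask shape {mask.shape} != volume shape {ref.shape}")
        mask_bool = np.asarray(mask.data) != 0

    # np.argwhere yields ascending lexicographic (i, j, k) order, the fixed
    # column linearization; boolean indexing below uses the same C order.
    mask_indices = np.argwhere(mask_bool)
    X = np.stack([np.asarray(v.data, dtype=np.float64)[mask_bool] for v in volumes])
    return CohortMatrix(X, labels, mask_indices, ref.shape, ref.affine.copy())
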