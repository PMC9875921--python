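"""Reading, writing and masked flattening of 3D brain-image volumes.

Volumes, analysis masks and atlas parcellations are NIfTI-1 images on a
shared grid.  All analysis happens on subjects × in-mask-voxel matrices;
the mask fixes a deterministic voxel ordering (0-based, row-major flatten
of the grid) so that matrices are reproducible across sessions and the
flatten/unflatten round trip is a bijection on in-mask voxels.

No resampling is performed: inputs are assumed already spatially
normalized, and two images are "grid compatible" only if their shapes are
identical and their affines agree elementwise within ``AFFINE_ATOL``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: elementwise tolerance for affine agreement between grid-compatible images
AFFINE_ATOL = 1e-4

#: required columns of a subject metadata table
METADATA_COLUMNS = ("subject_id", "group", "site", "scan_date", "mmse", "duration_years")


@dataclass
class VolumeGrid:
    """A scalar field over a 3D voxel grid with a voxel-to-world affine."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"non-3D image: got {self.values.ndim} dimensions")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def grids_compatible(a: "VolumeGrid | AnalysisMask | AtlasParcellation",
                     b: "VolumeGrid | AnalysisMask | AtlasParcellation") -> bool:
    """Identical shape and affines equal within :data:`AFFINE_ATOL`."""
    return (tuple(_shape_of(a)) == tuple(_shape_of(b))
            and np.allclose(a.affine, b.affine, atol=AFFINE_ATOL, rtol=0.0))


def _shape_of(obj) -> tuple[int, ...]:
    if isinstance(obj, VolumeGrid):
        return obj.values.shape
    if isinstance(obj, AnalysisMask):
        return obj.data.shape
    if isinstance(obj, AtlasParcellation):
        return obj.labels.shape
    raise TypeError(f"no grid on {type(obj)!r}")


def load_volume(path: str | Path) -> VolumeGrid:
    """Load a 3D NIfTI volume.  Raises on unreadable files and non-3D images."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"non-3D image: {path} has {data.ndim} dimensions")
    return VolumeGrid(values=data, affine=np.asarray(img.affine))


def save_volume(volume: VolumeGrid, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(volume.values.astype(np.float64), volume.affine), str(path))


@dataclass
class AnalysisMask:
    """Boolean analysis mask with a persisted in-mask voxel ordering.

    ``voxel_order`` is the strictly increasing list of row-major flat indices
    of in-mask voxels; column ``j`` of every masked matrix refers to
    ``voxel_order[j]``.
    """

    data: np.ndarray
    affine: np.ndarray
    voxel_order: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.voxel_order = np.flatnonzero(self.data.ravel(order="C"))
        if self.voxel_order.size < 2:
            raise ValueError("mask must contain at least 2 voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.voxel_order.size)

    def flatten(self, values: np.ndarray) -> np.ndarray:
        """Extract the in-mask voxels of a 3D array, in voxel_order."""
        values = np.asarray(values)
        if values.shape != self.data.shape:
            raise ValueError(f"shape {values.shape} does not match mask {self.data.shape}")
        return values.ravel(order="C")[self.voxel_order]

    def unflatten(self, vec: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place a masked vector back onto the full grid (``fill`` elsewhere)."""
        vec = np.asarray(vec)
        if vec.shape != (self.n_voxels,):
            raise ValueError(f"expected vector of length {self.n_voxels}, got {vec.shape}")
        out = np.full(self.data.size, fill, dtype=float)
        out[self.voxel_order] = vec
        return out.reshape(self.data.shape)

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisMask":
        img = nib.load(str(path))
        return cls(data=np.asarray(img.dataobj) > 0, affine=np.asarray(img.affine))


@dataclass
class AtlasParcellation:
    """Integer-labelled parcellation (0 = background) with a reference region.

    The reference region plays the pons role: regional activities are
    normalized to its mean, and it is excluded from pattern support.
    """

    labels: np.ndarray
    affine: np.ndarray
    roi_table: dict[int, str]
    reference_label: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        self.affine = np.asarray(self.affine, dtype=float)
        present = set(np.unique(self.labels).tolist()) - {0}
        if self.reference_label not in present:
            raise ValueError(f"reference label {self.reference_label} absent from atlas")
        missing = set(self.roi_table) - present
        if missing:
            raise ValueError(f"roi_table labels absent from atlas: {sorted(missing)}")

    @property
    def parcel_labels(self) -> list[int]:
        """Non-background, non-reference labels present in the field, sorted."""
        present = sorted(set(np.unique(self.labels).tolist()) - {0, self.reference_label})
        return [int(v) for v in present]

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int32), self.affine), str(path))


def extract_masked_matrix(volumes: Sequence[VolumeGrid], mask: AnalysisMask) -> np.ndarray:
    """Stack volumes into a subjects × in-mask-voxels matrix.

    Every in-mask value must be strictly positive (the downstream model is
    multiplicative and starts with a log transform); the first offending
    subject/voxel is reported.
    """
    rows = []
    for s, vol in enumerate(volumes):
        if not grids_compatible(vol, mask):
            raise ValueError(f"subject {s}: volume grid incompatible with mask")
        row = mask.flatten(vol.values)
        bad = ~(row > 0)
        if bad.any():
            j = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-positive in-mask value for subject {s} at voxel_order index {j} "
                f"(flat voxel {int(mask.voxel_order[j])}, value {row[j]!r})"
            )
        rows.append(row)
    return np.asarray(rows, dtype=float)


def roi_means(volume: VolumeGrid, atlas: AtlasParcellation, mask: AnalysisMask,
              labels: Sequence[int] | None = None) -> dict[int, float]:
    """Arithmetic mean of a volume over the in-mask voxels of each atlas label.

    Background (label 0) is excluded.  Labels with zero in-mask voxels are
    dropped with a logged warning rather than an error, so real atlases with
    cropped coverage still work.
    """
    if not grids_compatible(volume, mask) or not grids_compatible(atlas, mask):
        raise ValueError("volume/atlas grid incompatible with mask")
    lab = mask.flatten(atlas.labels).astype(np.int64)
    val = mask.flatten(volume.values)
    if labels is None:
        labels = sorted(set(np.unique(atlas.labels).tolist()) - {0})
    counts = np.bincount(lab[lab > 0], minlength=int(lab.max(initial=0)) + 1)
    sums = np.bincount(lab[lab > 0], weights=val[lab > 0],
                       minlength=int(lab.max(initial=0)) + 1)
    out: dict[int, float] = {}
    for label in labels:
        label = int(label)
        if label <= 0:
            continue
        if label >= counts.size or counts[label] == 0:
            logger.warning("ROI label %d has no in-mask voxels; dropped", label)
            continue
        out[label] = float(sums[label] / counts[label])
    return out


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a subject metadata CSV, checking the required column contract."""
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_matrix_tsv(matrix: np.ndarray, mask: AnalysisMask, path: str | Path,
                     subject_ids: Sequence[str] | None = None) -> None:
    """Export a subjects × voxels matrix as TSV with a voxel_order header."""
    cols = [str(int(v)) for v in mask.voxel_order]
    df = pd.DataFrame(matrix, columns=cols)
    if subject_ids is not None:
        df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, sep="\t", index=False)
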