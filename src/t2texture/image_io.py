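"""NIfTI volume/mask reading and per-case metric tables.

Volumes are plain 3D arrays of MR signal intensity in arbitrary units; the
NIfTI affine is carried through unchanged but never interpreted — every
computation in this package is a voxel-grid operation. Masks are "nonzero =
inside": a single binary lesion VOI per case, co-registered with its image.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DimensionalityError, GridMismatchError, ValidationError

__all__ = [
    "IntensityVolume",
    "VOIMask",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "write_metrics_table",
    "read_metrics_table",
]

METRICS_COLUMNS = ("case_id", "entropy", "edge_mean", "edge_median")


@dataclass(frozen=True)
class IntensityVolume:
    """A 3D scalar image with its (uninterpreted) spatial affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3 or min(data.shape) < 1:
            raise DimensionalityError(
                f"expected a 3D volume, got shape {np.asarray(self.data).shape}"
            )
        bad = int(np.size(data) - np.isfinite(data).sum())
        if bad:
            raise ValidationError(f"volume contains {bad} non-finite voxel(s)")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=np.float64))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class VOIMask:
    """Binary voxels-of-interest mask on the grid of its paired image."""

    data: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data).astype(bool)
        if data.ndim != 3:
            raise DimensionalityError(f"expected a 3D mask, got shape {data.shape}")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def require_nonempty(self) -> None:
        if self.n_voxels == 0:
            raise ValidationError("VOI mask is empty: at least one voxel is required")


def _squeeze_to_3d(data: np.ndarray, origin: str) -> np.ndarray:
    # tolerate e.g. (x, y, z, 1) exports; anything with >3 real axes is rejected
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{origin}: expected 3 non-singleton dimensions, got shape {data.shape}"
        )
    return data


def read_volume(path: str | os.PathLike) -> IntensityVolume:
    """Read a NIfTI (.nii/.nii.gz) scalar volume.

    A 4D array whose trailing dimensions are singletons is squeezed to 3D.
    Non-finite voxels are rejected with a count of the offending voxels.
    """
    img = nib.load(os.fspath(path))
    data = _squeeze_to_3d(np.asarray(img.get_fdata(), dtype=np.float64), str(path))
    return IntensityVolume(data=data, affine=np.asarray(img.affine))


def read_mask(path: str | os.PathLike, reference: IntensityVolume) -> VOIMask:
    """Read a NIfTI mask on the grid of ``reference``; nonzero means inside."""
    img = nib.load(os.fspath(path))
    data = _squeeze_to_3d(np.asarray(img.get_fdata(), dtype=np.float64), str(path))
    if data.shape != reference.shape:
        raise GridMismatchError(reference.shape, data.shape)
    mask = VOIMask(data=data != 0)
    mask.require_nonempty()
    return mask


def write_volume(volume: IntensityVolume, path: str | os.PathLike) -> None:
    nib.save(nib.Nifti1Image(volume.data, volume.affine), os.fspath(path))


def write_mask(mask: VOIMask, path: str | os.PathLike, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), os.fspath(path))


def write_metrics_table(
    records: Sequence[tuple[str, object]],
    path: str | os.PathLike,
    precision: int = 4,
) -> None:
    """Write ``(case_id, TextureMetrics)`` pairs as a TSV.

    Columns: case_id, entropy, edge_mean, edge_median; floats at fixed
    precision (default 4 decimals). Any object exposing the three metric
    attributes is accepted.
    """
    if len(records) == 0:
        raise ValidationError("no records to write")
    rows = [
        {
            "case_id": case_id,
            "entropy": m.entropy,
            "edge_mean": m.edge_mean,
            "edge_median": m.edge_median,
        }
        for case_id, m in records
    ]
    frame = pd.DataFrame(rows, columns=list(METRICS_COLUMNS))
    frame.to_csv(path, sep="\t", index=False, float_format=f"%.{precision}f")


def read_metrics_table(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(METRICS_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"metrics table missing columns: {sorted(missing)}")
    return frame
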