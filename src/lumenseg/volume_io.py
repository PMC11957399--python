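"""Volume containers and I/O.

Conventions: arrays are indexed (x, y, z) with z the axial (slice) axis,
0-based voxel indices, all physical distances in millimetres via the
per-axis ``spacing``.  Images are float32, label volumes are binary uint8.
NIfTI (.nii / .nii.gz) is the on-disk format.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["Volume", "LabelVolume", "SparseLabelVolume", "read_volume",
           "read_label_volume", "write_volume", "resample_isotropic",
           "normalize_intensity", "round_half_away"]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (0.5 -> 1)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _check_spacing(spacing: Sequence[float]) -> tuple:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive values, got {spacing}")
    return spacing


@dataclasses.dataclass
class Volume:
    """A 3-D scalar grid with voxel spacing (mm) and world origin (mm)."""

    values: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("volume must be a non-empty 3-D grid")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.values.shape


@dataclasses.dataclass
class LabelVolume(Volume):
    """Binary (0/1) label grid aligned with an image volume."""

    def __post_init__(self):
        super().__post_init__()
        vals = np.unique(self.values)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"label volume must be binary, found values {vals}")
        self.values = self.values.astype(np.uint8)


@dataclasses.dataclass
class SparseLabelVolume(LabelVolume):
    """Labels present only on a recorded subset of axial (z) slices."""

    labeled_slice_indices: tuple = ()

    def __post_init__(self):
        super().__post_init__()
        idx = tuple(int(i) for i in self.labeled_slice_indices)
        nz = self.shape[2]
        if any(i < 0 or i >= nz for i in idx):
            raise ValueError("labeled slice index outside the grid")
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate labeled slice indices")
        self.labeled_slice_indices = tuple(sorted(idx))


_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def write_volume(vol: Volume, path) -> Path:
    path = Path(path)
    if not _is_nifti(path):
        raise ValueError(f"unsupported volume format: {path.name} (use .nii/.nii.gz)")
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.values), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def read_volume(path) -> Volume:
    path = Path(path)
    if not _is_nifti(path):
        raise ValueError(f"unsupported volume format: {path.name} (use .nii/.nii.gz)")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(np.asarray(data), spacing, origin)


def read_label_volume(path, labeled_slice_indices=None):
    """Read a binary label volume; non-binary voxel values are rejected."""
    vol = read_volume(path)
    if labeled_slice_indices is None:
        return LabelVolume(vol.values, vol.spacing, vol.origin)
    return SparseLabelVolume(vol.values, vol.spacing, vol.origin,
                             tuple(labeled_slice_indices))


def resample_isotropic(vol: Volume, target_spacing: float = 1.0,
                       mode: str = "linear") -> Volume:
    """Resample to an isotropic grid.

    The new grid size per axis is round-half-away(old_size * old_spacing /
    target_spacing) — this reproduces, e.g., 512 px at 0.549 mm -> 281 px at
    1 mm and 198 slices at 2 mm -> 396 slices at 1 mm.  Images use linear
    interpolation, labels nearest-neighbour.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    old_shape = vol.shape
    new_shape = tuple(round_half_away(n * s / target_spacing)
                      for n, s in zip(old_shape, vol.spacing))
    if new_shape == old_shape and all(abs(s - target_spacing) < 1e-12
                                      for s in vol.spacing):
        out = vol.values.copy()
    else:
        factors = [nn / no for nn, no in zip(new_shape, old_shape)]
        order = 1 if mode == "linear" else 0
        out = ndimage.zoom(np.asarray(vol.values, dtype=np.float32), factors,
                           order=order, mode="nearest", grid_mode=True)
        assert out.shape == new_shape, (out.shape, new_shape)
    iso = (target_spacing,) * 3
    if isinstance(vol, SparseLabelVolume):
        scale = vol.spacing[2] / target_spacing
        idx = sorted({min(round_half_away(i * scale), new_shape[2] - 1)
                      for i in vol.labeled_slice_indices})
        return SparseLabelVolume(np.rint(out).astype(np.uint8), iso,
                                 vol.origin, tuple(idx))
    if isinstance(vol, LabelVolume):
        return LabelVolume(np.rint(out).astype(np.uint8), iso, vol.origin)
    return Volume(out, iso, vol.origin)


def normalize_intensity(vol: Volume, window=(-1000.0, 400.0)) -> Volume:
    """Clip to ``window`` then map affinely to [0, 1].

    The default window spans air-filled lumen through soft tissue in
    Hounsfield units.  Monotone non-decreasing, idempotent on [0, 1] input
    with window (0, 1).
    """
    low, high = float(window[0]), float(window[1])
    if low >= high:
        raise ValueError(f"window low must be < high, got {window}")
    vals = np.clip(np.asarray(vol.values, dtype=np.float32), low, high)
    vals = (vals - low) / (high - low)
    return Volume(vals, vol.spacing, vol.origin)
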