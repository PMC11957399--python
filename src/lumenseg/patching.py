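"""Patch planning, extraction, augmentation and probability stitching.

Training and inference both run on fixed-size patches laid out on a stride
grid (defaults 256x256x16 voxels with stride 128x128x8).  The last window
on each axis is clamped so it ends exactly at the volume border (every
emitted patch contains real data); volumes smaller than the patch in any
axis are symmetrically zero-padded first.  Overlapping probability patches
are merged by plain per-voxel averaging.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

__all__ = ["PatchGrid", "CutoutParams", "plan_patch_grid", "pad_to_min",
           "unpad", "extract_patch", "extract_patches", "augment_patch",
           "stitch_probabilities"]

DEFAULT_PATCH = (256, 256, 16)
DEFAULT_STRIDE = (128, 128, 8)


def _axis_offsets(size: int, patch: int, stride: int):
    if patch > size:
        raise ValueError(f"patch {patch} exceeds axis size {size}; pad first")
    offs = list(range(0, size - patch + 1, stride))
    if offs[-1] + patch < size:
        offs.append(size - patch)
    return tuple(offs)


@dataclasses.dataclass(frozen=True)
class PatchGrid:
    patch_size: tuple
    stride: tuple
    offsets: tuple          # per-axis strictly increasing offset tuples
    source_shape: tuple

    @property
    def positions(self):
        """All patch origin coordinates in row-major product order."""
        return tuple(itertools.product(*self.offsets))

    def __len__(self):
        return int(np.prod([len(o) for o in self.offsets]))

    def to_dict(self) -> dict:
        return {"patch_size": list(self.patch_size), "stride": list(self.stride),
                "offsets": [list(o) for o in self.offsets],
                "source_shape": list(self.source_shape)}


def plan_patch_grid(shape, patch_size=DEFAULT_PATCH,
                    stride=DEFAULT_STRIDE) -> PatchGrid:
    """Plan a fully covering stride grid over ``shape`` (clamp-last-window)."""
    offsets = tuple(_axis_offsets(n, p, s)
                    for n, p, s in zip(shape, patch_size, stride))
    return PatchGrid(tuple(patch_size), tuple(stride), offsets, tuple(shape))


def pad_to_min(values: np.ndarray, patch_size):
    """Symmetrically zero-pad axes smaller than the patch; returns (array, pad)."""
    pad = []
    for n, p in zip(values.shape, patch_size):
        deficit = max(0, p - n)
        pad.append((deficit // 2, deficit - deficit // 2))
    if any(lo or hi for lo, hi in pad):
        values = np.pad(values, pad)
    return values, tuple(pad)


def unpad(values: np.ndarray, pad) -> np.ndarray:
    slices = tuple(slice(lo, n - hi) for (lo, hi), n in zip(pad, values.shape))
    return values[slices]


def extract_patch(values: np.ndarray, origin, patch_size) -> np.ndarray:
    sl = tuple(slice(o, o + p) for o, p in zip(origin, patch_size))
    return values[sl]


def extract_patches(values: np.ndarray, grid: PatchGrid):
    return [extract_patch(values, pos, grid.patch_size) for pos in grid.positions]


@dataclasses.dataclass
class CutoutParams:
    """One axis-aligned cuboid of the image is zeroed with probability ``prob``.

    Edge lengths are drawn uniformly from [min_frac, max_frac] of each patch
    dimension; the label is never modified (fill 0 = post-window background).
    """

    prob: float = 0.5
    min_frac: float = 0.10
    max_frac: float = 0.25

    def validate(self, patch_shape) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("cutout prob must lie in [0, 1]")
        if not 0.0 < self.min_frac <= self.max_frac:
            raise ValueError("cutout fractions must be positive and ordered")
        if self.max_frac > 1.0:
            raise ValueError("cutout cuboid cannot exceed the patch")


def augment_patch(image: np.ndarray, label: np.ndarray | None,
                  flip_prob: float = 0.5,
                  cutout: CutoutParams | None = None, seed: int = 0):
    """Random per-axis flips (image and label together) plus image cut-out.

    Deterministic for a fixed seed.  Returns (image, label).
    """
    rng = np.random.default_rng(seed)
    img = np.asarray(image)
    lab = None if label is None else np.asarray(label)
    for ax in range(3):
        if rng.uniform() < flip_prob:
            img = np.flip(img, axis=ax)
            if lab is not None:
                lab = np.flip(lab, axis=ax)
    img = img.copy()
    lab = None if lab is None else lab.copy()
    if cutout is not None:
        cutout.validate(img.shape)
        if rng.uniform() < cutout.prob:
            sizes = [max(1, int(round(rng.uniform(cutout.min_frac, cutout.max_frac) * n)))
                     for n in img.shape]
            starts = [rng.integers(0, n - s + 1) for n, s in zip(img.shape, sizes)]
            sl = tuple(slice(st, st + sz) for st, sz in zip(starts, sizes))
            img[sl] = 0.0
    return img, lab


def stitch_probabilities(prob_patches, grid: PatchGrid, shape) -> np.ndarray:
    """Merge per-patch foreground probabilities by per-voxel averaging.

    ``prob_patches`` must contain one patch per grid position, in
    ``grid.positions`` order, each valued in [0, 1].
    """
    positions = grid.positions
    if len(prob_patches) != len(positions):
        raise ValueError(f"expected {len(positions)} patches, got {len(prob_patches)}")
    acc = np.zeros(shape, dtype=np.float64)
    cnt = np.zeros(shape, dtype=np.int32)
    for pos, patch in zip(positions, prob_patches):
        patch = np.asarray(patch)
        if patch.shape != grid.patch_size:
            raise ValueError("patch shape does not match grid patch_size")
        if patch.min() < 0 or patch.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        sl = tuple(slice(o, o + p) for o, p in zip(pos, grid.patch_size))
        acc[sl] += patch
        cnt[sl] += 1
    if (cnt == 0).any():
        raise ValueError("grid does not cover the volume")
    return (acc / cnt).astype(np.float32)
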