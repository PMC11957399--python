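"""Synthetic tubular CT phantoms.

Generates 3-D volumes containing elongated, folded tubes (intestine-lumen
stand-ins) on a noisy background, with dense, sparse (slice-wise) or absent
labels, plus a JSON dataset manifest splitting cases into labeled /
unlabeled training cases and sparsely labeled test cases.  Centerlines are
bounded-turn 3-D random walks, smoothed and rasterized, then inflated to a
tube by thresholding a Euclidean distance transform.  Identical
(spec, seed) pairs produce bit-identical volumes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import (LabelVolume, SparseLabelVolume, Volume,
                        round_half_away, write_volume)

__all__ = ["PhantomSpec", "CaseEntry", "DatasetManifest", "generate_phantom",
           "sparsify_labels", "make_dataset",
           "SPARSE_FRACTION_RANGE"]

# Fraction of axial slices carrying labels on sparsely annotated test cases.
SPARSE_FRACTION_RANGE = (0.0100, 0.0531)


@dataclasses.dataclass
class PhantomSpec:
    """Geometry and intensity parameters of a synthetic phantom.

    Intensities are in normalized units in [0, 1]; the lumen renders darker
    than the background by default (air-like).  ``contact_probability`` is
    the chance that a new tube is forced to start within 2 voxels of an
    existing tube, producing touching-lumen configurations.
    """

    grid_shape: tuple = (96, 96, 32)
    spacing: tuple = (1.0, 1.0, 1.0)
    n_tubes: int = 3
    radius_range: tuple = (2.0, 4.0)
    lumen_intensity: float = 0.25
    background_intensity: float = 0.65
    noise_sd: float = 0.05
    contact_probability: float = 0.25

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if any(float(s) <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        rmin, rmax = self.radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("radius_range must be positive and ordered")
        if any(n < 2 * rmax + 2 for n in self.grid_shape):
            raise ValueError("grid_shape must be at least 2*max_radius + 2 per axis")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("lumen_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.contact_probability <= 1.0:
            raise ValueError("contact_probability must lie in [0, 1]")
        if self.n_tubes < 1:
            raise ValueError("need at least one tube")


_MAX_TURN = math.tan(math.pi / 6)  # per-step direction change bounded to 30 degrees


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _walk_centerline(rng, start, shape, margin, n_steps):
    """Bounded-turn unit-step random walk, reflected at the grid margins."""
    pos = np.asarray(start, dtype=float)
    d = _random_unit(rng)
    pts = [pos.copy()]
    lo = np.full(3, margin, dtype=float)
    hi = np.asarray(shape, dtype=float) - 1 - margin
    for _ in range(n_steps):
        g = rng.normal(0.0, 0.35, size=3)
        perp = g - np.dot(g, d) * d
        norm = np.linalg.norm(perp)
        if norm > _MAX_TURN:
            perp *= _MAX_TURN / norm
        d = d + perp
        d /= np.linalg.norm(d)
        nxt = pos + d
        for ax in range(3):
            if nxt[ax] < lo[ax] or nxt[ax] > hi[ax]:
                d[ax] = -d[ax]
                nxt[ax] = pos[ax] + d[ax]
        pos = np.clip(nxt, lo, hi)
        pts.append(pos.copy())
    return np.asarray(pts)


def _smooth_path(pts: np.ndarray, window: int = 5) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(pts, ((pad, pad), (0, 0)), mode="edge")
    return np.stack([np.convolve(padded[:, ax], kernel, mode="valid")
                     for ax in range(3)], axis=1)


def _rasterize_tube(path: np.ndarray, radius: float, shape) -> np.ndarray:
    center = np.zeros(shape, dtype=bool)
    idx = np.rint(path).astype(int)
    idx = np.clip(idx, 0, np.asarray(shape) - 1)
    center[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    dist = ndimage.distance_transform_edt(~center)
    return dist <= radius


def generate_phantom(spec: PhantomSpec, seed: int, return_tubes: bool = False):
    """Generate one (image, dense label) phantom pair.

    Returns ``(Volume, LabelVolume)``; with ``return_tubes=True`` also the
    list of individual boolean tube masks (before union).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    n_steps = int(2.5 * max(shape))
    tubes, centerpaths = [], []
    for i in range(spec.n_tubes):
        radius = rng.uniform(*spec.radius_range)
        margin = math.ceil(radius) + 1
        if centerpaths and rng.uniform() < spec.contact_probability:
            prev = centerpaths[rng.integers(len(centerpaths))]
            anchor = prev[rng.integers(len(prev))]
            start = anchor + rng.uniform(-2, 2, size=3)
            start = np.clip(start, margin, np.asarray(shape) - 1 - margin)
        else:
            start = rng.uniform(margin, np.asarray(shape) - 1 - margin)
        path = _smooth_path(_walk_centerline(rng, start, shape, margin, n_steps))
        centerpaths.append(path)
        tubes.append(_rasterize_tube(path, radius, shape))
    label = np.zeros(shape, dtype=np.uint8)
    for t in tubes:
        label |= t.astype(np.uint8)
    image = np.full(shape, spec.background_intensity, dtype=np.float32)
    image[label == 1] = spec.lumen_intensity
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, shape).astype(np.float32)
    vol = Volume(image.astype(np.float32), spec.spacing)
    lab = LabelVolume(label, spec.spacing)
    if return_tubes:
        return vol, lab, tubes
    return vol, lab


def sparsify_labels(label: LabelVolume, slice_fraction: float,
                    seed: int) -> SparseLabelVolume:
    """Keep labels on a random subset of axial slices, zero the rest.

    round(slice_fraction * Z) slices (at least one) are chosen uniformly
    without replacement; retained slices are voxel-identical to the dense
    input and their indices are recorded.
    """
    if not 0.0 < slice_fraction <= 1.0:
        raise ValueError("slice_fraction must lie in (0, 1]")
    if label.values.size == 0:
        raise ValueError("empty label volume")
    nz = label.shape[2]
    n_keep = max(1, round_half_away(slice_fraction * nz))
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(nz, size=min(n_keep, nz), replace=False))
    sparse = np.zeros_like(label.values)
    sparse[:, :, keep] = label.values[:, :, keep]
    return SparseLabelVolume(sparse, label.spacing, label.origin, tuple(keep))


@dataclasses.dataclass
class CaseEntry:
    case_id: str
    image_path: str
    label_path: str | None
    annotation: str           # dense | sparse | unlabeled
    split: str                # train | test
    seed: int
    labeled_slice_indices: tuple = ()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["labeled_slice_indices"] = list(self.labeled_slice_indices)
        return d


@dataclasses.dataclass
class DatasetManifest:
    cases: list

    def __post_init__(self):
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise ValueError("case_ids must be unique")
        for c in self.cases:
            if c.annotation == "unlabeled" and c.label_path is not None:
                raise ValueError(f"unlabeled case {c.case_id} must not carry a label path")

    def select(self, annotation=None, split=None):
        out = self.cases
        if annotation is not None:
            out = [c for c in out if c.annotation == annotation]
        if split is not None:
            out = [c for c in out if c.split == split]
        return list(out)

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({"cases": [c.to_dict() for c in self.cases]},
                                   indent=1))
        return path

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        raw = json.loads(Path(path).read_text())
        cases = []
        for d in raw["cases"]:
            d["labeled_slice_indices"] = tuple(d.get("labeled_slice_indices", ()))
            cases.append(CaseEntry(**d))
        return cls(cases)


def make_dataset(n_dense: int, n_unlabeled: int, n_test: int,
                 spec: PhantomSpec, seed: int, out_dir) -> DatasetManifest:
    """Write a phantom dataset (NIfTI images/labels + JSON manifest) to disk.

    Training cases are densely labeled or unlabeled; test cases carry sparse
    slice-wise labels with labeled-slice fractions drawn from
    ``SPARSE_FRACTION_RANGE``.
    """
    if min(n_dense, n_unlabeled, n_test) < 0:
        raise ValueError("case counts must be non-negative")
    spec.validate()
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_total = n_dense + n_unlabeled + n_test
    case_seeds = rng.integers(0, 2**31 - 1, size=2 * n_total)
    cases = []
    k = 0
    roles = ([("dense", "train")] * n_dense + [("unlabeled", "train")] * n_unlabeled
             + [("sparse", "test")] * n_test)
    for i, (annotation, split) in enumerate(roles):
        case_id = f"case_{i:03d}_{annotation}"
        gen_seed = int(case_seeds[k]); k += 1
        aux_seed = int(case_seeds[k]); k += 1
        vol, lab = generate_phantom(spec, gen_seed)
        img_path = out_dir / "images" / f"{case_id}.nii.gz"
        write_volume(vol, img_path)
        label_path = None
        slice_idx = ()
        if annotation == "dense":
            label_path = out_dir / "labels" / f"{case_id}.nii.gz"
            write_volume(lab, label_path)
        elif annotation == "sparse":
            frac = float(np.random.default_rng(aux_seed).uniform(*SPARSE_FRACTION_RANGE))
            sparse = sparsify_labels(lab, frac, aux_seed + 1)
            label_path = out_dir / "labels" / f"{case_id}.nii.gz"
            write_volume(sparse, label_path)
            slice_idx = sparse.labeled_slice_indices
        cases.append(CaseEntry(case_id, str(img_path),
                               None if label_path is None else str(label_path),
                               annotation, split, gen_seed, slice_idx))
    manifest = DatasetManifest(cases)
    manifest.save(out_dir / "manifest.json")
    return manifest
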