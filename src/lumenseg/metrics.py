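"""Segmentation evaluation.

Overlap metrics (Dice, precision, recall, all in percent), the normalized
surface Dice (NSD) at a 3.0 mm tolerance, the sparse-slice evaluation
protocol (confusion counts pooled over the labeled axial slices only), and
mean ± SD aggregation over repeated runs.

Conventions for empty masks: a metric whose denominator is zero is
reported as NaN, and NaN entries are excluded from averaging; a case with
empty prediction *and* empty ground truth is entirely undefined.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import SparseLabelVolume

__all__ = ["CaseMetrics", "overlap_metrics", "nsd", "evaluate_sparse_case",
           "evaluate_dense_case", "aggregate_runs", "write_metrics_csv"]

NSD_TOLERANCE_MM = 3.0


@dataclasses.dataclass
class CaseMetrics:
    case_id: str
    dice: float
    precision: float
    recall: float
    nsd: float

    def as_row(self):
        return [self.case_id] + [f"{v:.4f}" for v in
                                 (self.dice, self.precision, self.recall, self.nsd)]


def _confusion(pred: np.ndarray, gt: np.ndarray):
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.logical_and(pred, gt).sum())
    fp = int(np.logical_and(pred, ~gt).sum())
    fn = int(np.logical_and(~pred, gt).sum())
    return tp, fp, fn


def _ratios(tp, fp, fn):
    dice = 100.0 * 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else np.nan
    precision = 100.0 * tp / (tp + fp) if (tp + fp) else np.nan
    recall = 100.0 * tp / (tp + fn) if (tp + fn) else np.nan
    return dice, precision, recall


def overlap_metrics(pred, gt):
    """(Dice, precision, recall) in percent; NaN where undefined."""
    return _ratios(*_confusion(pred, gt))


def _surface(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels under 6-connectivity; volume-border voxels count."""
    mask = np.asarray(mask).astype(bool)
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure, border_value=0)
    return mask & ~interior


def nsd(pred, gt, spacing=(1.0, 1.0, 1.0),
        tolerance: float = NSD_TOLERANCE_MM) -> float:
    """Normalized surface Dice in percent.

    Fraction of the two masks' boundary surfaces lying within ``tolerance``
    millimetres of each other; symmetric in (pred, gt).  NaN if both masks
    are empty.
    """
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    sp = _surface(pred)
    sg = _surface(gt)
    n_p, n_g = int(sp.sum()), int(sg.sum())
    if n_p + n_g == 0:
        return np.nan
    if n_p == 0 or n_g == 0:
        return 0.0
    dist_to_g = ndimage.distance_transform_edt(~sg, sampling=spacing)
    dist_to_p = ndimage.distance_transform_edt(~sp, sampling=spacing)
    close_p = int((dist_to_g[sp] <= tolerance).sum())
    close_g = int((dist_to_p[sg] <= tolerance).sum())
    return 100.0 * (close_p + close_g) / (n_p + n_g)


def evaluate_sparse_case(case_id: str, pred3d: np.ndarray,
                         sparse_gt: SparseLabelVolume,
                         tolerance: float = NSD_TOLERANCE_MM) -> CaseMetrics:
    """Evaluate a 3-D prediction against slice-wise sparse labels.

    Confusion counts are pooled over the labeled axial slices only and the
    ratios computed per case; unlabeled slices are ignored entirely.  NSD
    is computed on the sub-volume formed by gathering the labeled slices
    (an approximation, since surfaces across missing slices are unknown).
    """
    idx = list(sparse_gt.labeled_slice_indices)
    if not idx:
        raise ValueError("sparse case has no labeled slices")
    pred3d = np.asarray(pred3d).astype(bool)
    if pred3d.shape != sparse_gt.shape:
        raise ValueError("prediction/label shape mismatch")
    pred_sub = pred3d[:, :, idx]
    gt_sub = sparse_gt.values[:, :, idx].astype(bool)
    dice, precision, recall = overlap_metrics(pred_sub, gt_sub)
    surf = nsd(pred_sub, gt_sub, sparse_gt.spacing, tolerance)
    return CaseMetrics(case_id, dice, precision, recall, surf)


def evaluate_dense_case(case_id: str, pred3d: np.ndarray, gt,
                        tolerance: float = NSD_TOLERANCE_MM) -> CaseMetrics:
    dice, precision, recall = overlap_metrics(pred3d, gt.values)
    surf = nsd(pred3d, gt.values, gt.spacing, tolerance)
    return CaseMetrics(case_id, dice, precision, recall, surf)


def aggregate_runs(per_run_case_metrics):
    """Aggregate repeated experiments: mean over cases within each run,
    then mean and population SD across runs.

    ``per_run_case_metrics``: list (runs) of lists of :class:`CaseMetrics`.
    Returns {metric: (mean, sd)}.
    """
    if not per_run_case_metrics:
        raise ValueError("need at least one run")
    out = {}
    for metric in ("dice", "precision", "recall", "nsd"):
        run_means = []
        for run in per_run_case_metrics:
            vals = np.asarray([getattr(c, metric) for c in run], dtype=float)
            vals = vals[~np.isnan(vals)]
            run_means.append(vals.mean() if vals.size else np.nan)
        run_means = np.asarray(run_means, dtype=float)
        ok = run_means[~np.isnan(run_means)]
        if ok.size:
            out[metric] = (float(ok.mean()), float(ok.std(ddof=0)))
        else:
            out[metric] = (np.nan, np.nan)
    return out


def write_metrics_csv(path, case_metrics, aggregate: bool = True) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "dice", "precision", "recall", "nsd"])
        for cm in case_metrics:
            writer.writerow(cm.as_row())
        if aggregate and case_metrics:
            agg = aggregate_runs([list(case_metrics)])
            writer.writerow(["mean"] + [f"{agg[m][0]:.4f}" for m in
                                        ("dice", "precision", "recall", "nsd")])
    return path
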