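"""Loss terms for co-trained semi-supervised segmentation.

The supervised loss on labeled patches is an alpha-weighted sum of soft
Dice and soft centerline-Dice (clDice); the unsupervised loss on unlabeled
patches is the Dice loss against the partner network's pseudo-label,
scaled by a distance weight — the mean of the min-max-normalized Euclidean
distance transform of that pseudo-label, which down-weights
boundary-dominated (less reliable) pseudo-labels.  The unsupervised terms
ramp in over training as gamma(t) = 0.1 * exp(-5 (1 - t/T)).

Probabilities enter as autodiff tensors (:class:`lumenseg.nn.Tensor`) so
every term is differentiable; pseudo-labels and distance maps are plain
arrays and never carry gradient.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .nn import Tensor, as_tensor, minimum, maximum, relu, shift_clamp

__all__ = ["SupervisedLossConfig", "DistanceWeightMap", "soft_dice_loss",
           "soft_skeleton", "soft_skeleton_np", "soft_cl_dice_loss",
           "supervised_loss", "distance_weight", "unsupervised_loss",
           "ramp_gamma", "total_loss"]

EPS = 1e-5


@dataclasses.dataclass
class SupervisedLossConfig:
    """alpha blends Dice vs clDice; k is the soft-skeleton iteration count."""

    alpha: float = 0.5
    eps: float = EPS
    skeleton_iters: int = 5

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.skeleton_iters < 1:
            raise ValueError("skeleton_iters must be >= 1")


def _check_shapes(prob, target) -> None:
    if tuple(prob.shape) != tuple(np.asarray(target).shape):
        raise ValueError(f"shape mismatch: {tuple(prob.shape)} vs "
                         f"{tuple(np.asarray(target).shape)}")


def soft_dice_loss(prob, target, eps: float = EPS) -> Tensor:
    """1 - (2 sum(p g) + eps) / (sum p + sum g + eps) on the foreground map."""
    prob = as_tensor(prob)
    target = np.asarray(target, dtype=np.float32)
    _check_shapes(prob, target)
    inter = (prob * Tensor(target)).sum()
    denom = prob.sum() + float(target.sum()) + eps
    return 1.0 - (2.0 * inter + eps) / denom


def _pool1d(x, axis: int, use_max: bool):
    lo = shift_clamp(x, axis, -1)
    hi = shift_clamp(x, axis, +1)
    op = maximum if use_max else minimum
    return op(op(lo, x), hi)


def _soft_erode(x):
    # min over the three axis-aligned 1-D windows (clDice-style 3-D erosion)
    p1 = _pool1d(x, x.ndim - 3, False)
    p2 = _pool1d(x, x.ndim - 2, False)
    p3 = _pool1d(x, x.ndim - 1, False)
    return minimum(minimum(p1, p2), p3)


def _soft_dilate(x):
    # full 3x3x3 max pooling, separable
    for ax in (x.ndim - 3, x.ndim - 2, x.ndim - 1):
        x = _pool1d(x, ax, True)
    return x


def _soft_open(x):
    return _soft_dilate(_soft_erode(x))


def soft_skeleton(prob, k: int) -> Tensor:
    """Iterative soft morphological skeletonization (k erosion rounds).

    Alternates soft erosion with soft opening, accumulating the ridge
    residual relu(img - open(img)); on binary tubes of radius <= k the
    result concentrates on the medial axis.  Differentiable.
    """
    if k < 1:
        raise ValueError("skeleton iterations must be >= 1")
    img = as_tensor(prob)
    skel = relu(img - _soft_open(img))
    for _ in range(k):
        img = _soft_erode(img)
        delta = relu(img - _soft_open(img))
        skel = skel + relu(delta - skel * delta)
    return skel


def _np_pool1d(x, axis, use_max):
    n = x.shape[axis]
    lo = np.take(x, np.clip(np.arange(n) - 1, 0, n - 1), axis=axis)
    hi = np.take(x, np.clip(np.arange(n) + 1, 0, n - 1), axis=axis)
    op = np.maximum if use_max else np.minimum
    return op(op(lo, x), hi)


def soft_skeleton_np(arr: np.ndarray, k: int) -> np.ndarray:
    """Gradient-free mirror of :func:`soft_skeleton` for constant inputs."""
    if k < 1:
        raise ValueError("skeleton iterations must be >= 1")
    arr = np.asarray(arr, dtype=np.float32)
    axes = (arr.ndim - 3, arr.ndim - 2, arr.ndim - 1)

    def erode(x):
        pools = [_np_pool1d(x, ax, False) for ax in axes]
        return np.minimum(np.minimum(pools[0], pools[1]), pools[2])

    def opening(x):
        y = erode(x)
        for ax in axes:
            y = _np_pool1d(y, ax, True)
        return y

    img = arr
    skel = np.maximum(img - opening(img), 0.0)
    for _ in range(k):
        img = erode(img)
        delta = np.maximum(img - opening(img), 0.0)
        skel = skel + np.maximum(delta - skel * delta, 0.0)
    return skel


def soft_cl_dice_loss(prob, target, k: int = 5, eps: float = EPS) -> Tensor:
    """Centerline Dice loss: 1 - 2 Tprec Tsens / (Tprec + Tsens + eps).

    Tprec measures how much of the prediction's skeleton lies inside the
    ground truth; Tsens how much of the ground truth's skeleton the
    prediction recovers.  The target's skeleton is a constant and carries
    no gradient.
    """
    prob = as_tensor(prob)
    target = np.asarray(target, dtype=np.float32)
    _check_shapes(prob, target)
    skel_p = soft_skeleton(prob, k)
    skel_g = soft_skeleton_np(target, k)
    tprec = ((skel_p * Tensor(target)).sum() + eps) / (skel_p.sum() + eps)
    tsens = ((Tensor(skel_g) * prob).sum() + eps) / (float(skel_g.sum()) + eps)
    cl = 2.0 * tprec * tsens / (tprec + tsens + eps)
    return 1.0 - cl


def supervised_loss(prob, target, cfg: SupervisedLossConfig | None = None) -> Tensor:
    """alpha * Dice loss + (1 - alpha) * clDice loss."""
    cfg = cfg or SupervisedLossConfig()
    cfg.validate()
    dice = soft_dice_loss(prob, target, cfg.eps)
    if cfg.alpha == 1.0:
        return dice
    cl = soft_cl_dice_loss(prob, target, cfg.skeleton_iters, cfg.eps)
    if cfg.alpha == 0.0:
        return cl
    return cfg.alpha * dice + (1.0 - cfg.alpha) * cl


@dataclasses.dataclass
class DistanceWeightMap:
    """Min-max-normalized EDT of a pseudo-label and its scalar mean weight."""

    values: np.ndarray
    weight: float

    def __post_init__(self):
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("distance map values must lie in [0, 1]")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")


def distance_weight(pseudo: np.ndarray) -> DistanceWeightMap:
    """Distance weighting of a binary pseudo-label (no gradient).

    Foreground voxels receive the Euclidean distance (voxel units) to the
    nearest background voxel, background voxels 0; the map is min-max
    normalized per patch and its mean is the scalar weight.  Degenerate
    conventions: all-background -> weight 0; all-foreground -> weight 1.
    """
    pseudo = np.asarray(pseudo)
    if not np.isin(np.unique(pseudo), (0, 1)).all():
        raise ValueError("pseudo-label must be binary")
    if pseudo.sum() == 0:
        return DistanceWeightMap(np.zeros(pseudo.shape, dtype=np.float32), 0.0)
    if pseudo.all():
        return DistanceWeightMap(np.ones(pseudo.shape, dtype=np.float32), 1.0)
    edt = ndimage.distance_transform_edt(pseudo)
    mn, mx = edt.min(), edt.max()
    norm = (edt - mn) / (mx - mn)
    return DistanceWeightMap(norm.astype(np.float32), float(norm.mean()))


def unsupervised_loss(prob_u, pseudo_other: np.ndarray,
                      dmap: DistanceWeightMap, eps: float = EPS) -> Tensor:
    """Mean over voxels of Dice(prob, pseudo) * D(x,y,z).

    Because the Dice loss is a per-patch scalar this equals
    Dice * mean(D) = Dice * weight; the pseudo-label and map are constants.
    """
    pseudo_other = np.asarray(pseudo_other)
    if tuple(dmap.values.shape) != tuple(pseudo_other.shape):
        raise ValueError("distance map shape does not match pseudo-label")
    return soft_dice_loss(prob_u, pseudo_other, eps) * dmap.weight


def ramp_gamma(t: float, total: float) -> float:
    """Unsupervised-loss ramp: 0.1 * exp(-5 (1 - t/T)); equals 0.1 at t = T."""
    if total <= 0:
        raise ValueError("total iterations must be positive")
    if not 0 <= t <= total:
        raise ValueError("iteration t must lie in [0, T]")
    return 0.1 * float(np.exp(-5.0 * (1.0 - t / total)))


def total_loss(prob1_l, prob2_l, gt, prob1_u, prob2_u,
               pseudo1, pseudo2, d1: DistanceWeightMap, d2: DistanceWeightMap,
               t: float, total: float,
               cfg: SupervisedLossConfig | None = None):
    """Four-term co-training loss.

    Lsup(net1, G) + Lsup(net2, G) + gamma [ Lun(net1_u, P2*, D2)
    + Lun(net2_u, P1*, D1) ] — each network's unlabeled prediction is
    scored against the *other* network's pseudo-label and distance map.
    Returns (loss tensor, components dict).
    """
    cfg = cfg or SupervisedLossConfig()
    gamma = ramp_gamma(t, total)
    sup1 = supervised_loss(prob1_l, gt, cfg)
    sup2 = supervised_loss(prob2_l, gt, cfg)
    un1 = unsupervised_loss(prob1_u, pseudo2, d2, cfg.eps)
    un2 = unsupervised_loss(prob2_u, pseudo1, d1, cfg.eps)
    loss = sup1 + sup2 + gamma * un1 + gamma * un2
    parts = {"gamma": gamma, "l_sup1": float(sup1.data), "l_sup2": float(sup2.data),
             "l_un1": float(un1.data), "l_un2": float(un2.data),
             "l_total": float(loss.data)}
    return loss, parts
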