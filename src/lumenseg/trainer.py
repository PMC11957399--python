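"""Bidirectional teaching: co-training two networks with cross pseudo-labels.

Two identically configured networks with different initial weights are
trained simultaneously.  Each iteration feeds a labeled and an unlabeled
patch batch to both networks; every network is supervised on the labeled
batch by the ground truth and on the unlabeled batch by the *other*
network's argmax pseudo-label, weighted by the pseudo-label's distance
weight and the gamma(t) ramp.  Pseudo-labels and distance maps are
gradient-detached, so each network's update never differentiates through
its teacher.  SGD with momentum and a poly learning-rate schedule; the
final-iteration model is kept (no model selection).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from . import losses as L
from .model import LMVSNet, NetConfig
from .nn import SGD, Tensor, narrow, poly_lr, take_index
from .patching import (CutoutParams, augment_patch, extract_patch,
                       pad_to_min, plan_patch_grid, stitch_probabilities,
                       unpad)
from .phantom import DatasetManifest
from .volume_io import (Volume, read_label_volume, read_volume,
                        resample_isotropic)

__all__ = ["TrainConfig", "NetworkPair", "TrainResult", "make_pseudo_label",
           "training_step", "train", "predict_volume", "save_checkpoint",
           "load_checkpoint"]

LOG_COLUMNS = ("iteration", "lr", "gamma", "l_sup1", "l_sup2", "l_un1",
               "l_un2", "l_total")


@dataclasses.dataclass
class TrainConfig:
    """Training hyper-parameters.

    Defaults follow the reference recipe: 8 labeled + 8 unlabeled patches
    per iteration, SGD momentum 0.9, lr0 = 0.01 with poly power 0.9 over
    30,000 iterations, patches 256x256x16 on a 128x128x8 stride.  All of it
    scales down for small phantoms.
    """

    labeled_batch: int = 8
    unlabeled_batch: int = 8
    lr0: float = 0.01
    poly_power: float = 0.9
    momentum: float = 0.9
    weight_decay: float = 1e-4
    total_iters: int = 30_000
    seed_net1: int = 1
    seed_net2: int = 2
    seed_data: int = 0
    alpha: float = 0.5
    skeleton_iters: int = 5
    patch_size: tuple = (256, 256, 16)
    stride: tuple = (128, 128, 8)
    flip_prob: float = 0.5
    cutout: CutoutParams = dataclasses.field(default_factory=CutoutParams)
    fg_oversample: float = 0.5
    unsupervised_weight_scale: float = 1.0   # 0 -> supervised-only training
    target_spacing: float = 1.0
    net_config: NetConfig = dataclasses.field(default_factory=NetConfig)

    def validate(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.total_iters < 1:
            raise ValueError("total_iters must be >= 1")
        if self.seed_net1 == self.seed_net2:
            raise ValueError("the two network seeds must differ")
        if self.labeled_batch < 1:
            raise ValueError("need at least one labeled patch per iteration")

    def loss_config(self) -> L.SupervisedLossConfig:
        return L.SupervisedLossConfig(self.alpha, L.EPS, self.skeleton_iters)


@dataclasses.dataclass
class NetworkPair:
    net1: LMVSNet
    net2: LMVSNet


@dataclasses.dataclass
class TrainResult:
    pair: NetworkPair
    log: list
    checkpoint_path: Path | None = None


def make_pseudo_label(prob) -> np.ndarray:
    """Argmax binarization of two-channel softmax output (ties -> background).

    Accepts (2, ...) or (N, 2, ...) probabilities; gradient-free output.
    """
    data = prob.data if isinstance(prob, Tensor) else np.asarray(prob)
    ch_axis = 0 if data.ndim == 4 else 1
    if data.shape[ch_axis] != 2:
        raise ValueError(f"expected 2 channels on axis {ch_axis}, got shape {data.shape}")
    fg = np.take(data, 1, axis=ch_axis)
    bg = np.take(data, 0, axis=ch_axis)
    return (fg > bg).astype(np.uint8)


def _per_sample_unsupervised(prob_fg, pseudos, dmaps):
    terms = [L.unsupervised_loss(take_index(prob_fg, b, 0), pseudos[b], dmaps[b])
             for b in range(prob_fg.shape[0])]
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def training_step(pair: NetworkPair, labeled_batch, unlabeled_batch,
                  t: int, cfg: TrainConfig, opt1: SGD | None = None,
                  opt2: SGD | None = None) -> dict:
    """One co-training iteration; returns the loss components and gamma.

    ``labeled_batch``: (images (B,1,X,Y,Z), labels (B,X,Y,Z) binary);
    ``unlabeled_batch``: images (B,1,X,Y,Z) or None.  If optimizers are
    given, one SGD update per network is applied.
    """
    imgs_l, labels = labeled_batch
    if imgs_l.shape[0] == 0:
        raise ValueError("labeled batch must be non-empty (supervised anchor)")
    cfg_loss = cfg.loss_config()
    gamma = L.ramp_gamma(t, cfg.total_iters) * cfg.unsupervised_weight_scale
    n_l = imgs_l.shape[0]
    use_unlabeled = (unlabeled_batch is not None
                     and unlabeled_batch.shape[0] > 0 and gamma > 0)
    # one forward per network on the concatenated labeled+unlabeled block
    x = Tensor(np.concatenate([imgs_l, unlabeled_batch])
               if use_unlabeled else imgs_l)
    f1 = take_index(pair.net1(x), 1, 1)
    f2 = take_index(pair.net2(x), 1, 1)
    p1_l = narrow(f1, 0, 0, n_l)
    p2_l = narrow(f2, 0, 0, n_l)
    # supervised losses pooled over the batch block (batch Dice / clDice)
    sup1 = L.supervised_loss(p1_l, labels, cfg_loss)
    sup2 = L.supervised_loss(p2_l, labels, cfg_loss)

    if use_unlabeled:
        n_u = unlabeled_batch.shape[0]
        p1_u = narrow(f1, 0, n_l, n_u)
        p2_u = narrow(f2, 0, n_l, n_u)
        pseudo1 = [make_pseudo_label(np.stack([1 - p, p]))
                   for p in p1_u.data]           # detached by construction
        pseudo2 = [make_pseudo_label(np.stack([1 - p, p])) for p in p2_u.data]
        d1 = [L.distance_weight(p) for p in pseudo1]
        d2 = [L.distance_weight(p) for p in pseudo2]
        un1 = _per_sample_unsupervised(p1_u, pseudo2, d2)
        un2 = _per_sample_unsupervised(p2_u, pseudo1, d1)
        loss = sup1 + sup2 + gamma * un1 + gamma * un2
        un1_v, un2_v = float(un1.data), float(un2.data)
    else:
        loss = sup1 + sup2
        un1_v = un2_v = 0.0

    if opt1 is not None and opt2 is not None:
        opt1.zero_grad()
        opt2.zero_grad()
        loss.backward()
        opt1.step()
        opt2.step()

    return {"gamma": gamma, "l_sup1": float(sup1.data),
            "l_sup2": float(sup2.data), "l_un1": un1_v, "l_un2": un2_v,
            "l_total": float(loss.data)}


class _Sampler:
    """Random patch sampler over in-memory cases, with foreground oversampling."""

    def __init__(self, cases, cfg: TrainConfig, rng):
        self.cfg = cfg
        self.rng = rng
        self.cases = []
        for image, label in cases:
            padded, pad = pad_to_min(image, cfg.patch_size)
            lab_p = None
            if label is not None:
                lab_p, _ = pad_to_min(label, cfg.patch_size)
            grid = plan_patch_grid(padded.shape, cfg.patch_size, cfg.stride)
            positions = grid.positions
            fg_positions = positions
            if lab_p is not None:
                fg = [pos for pos in positions
                      if extract_patch(lab_p, pos, cfg.patch_size).any()]
                fg_positions = fg or positions
            self.cases.append((padded, lab_p, positions, fg_positions))

    def sample(self, n: int, labeled: bool):
        imgs, labs = [], []
        for _ in range(n):
            img, lab, positions, fg_positions = \
                self.cases[self.rng.integers(len(self.cases))]
            pool = positions
            if labeled and self.rng.uniform() < self.cfg.fg_oversample:
                pool = fg_positions
            pos = pool[self.rng.integers(len(pool))]
            ip = extract_patch(img, pos, self.cfg.patch_size)
            lp = None if lab is None else extract_patch(lab, pos, self.cfg.patch_size)
            ip, lp = augment_patch(ip, lp, self.cfg.flip_prob, self.cfg.cutout,
                                   seed=int(self.rng.integers(2**31 - 1)))
            imgs.append(ip)
            if lp is not None:
                labs.append(lp)
        imgs = np.stack(imgs)[:, None].astype(np.float32)
        return (imgs, np.stack(labs).astype(np.uint8)) if labeled else imgs


def _load_cases(manifest: DatasetManifest):
    labeled, unlabeled = [], []
    for case in manifest.select(split="train"):
        image = read_volume(case.image_path).values.astype(np.float32)
        if case.annotation == "dense":
            label = read_label_volume(case.label_path).values
            labeled.append((image, label))
        else:
            unlabeled.append((image, None))
    return labeled, unlabeled


def train(cfg: TrainConfig, manifest: DatasetManifest,
          out_dir=None) -> TrainResult:
    """Run bidirectional teaching to the final iteration.

    Fully reproducible given (seed_net1, seed_net2, seed_data).  Writes a
    CSV training log and a final-iteration checkpoint when ``out_dir`` is
    given.
    """
    cfg.validate()
    labeled_cases, unlabeled_cases = _load_cases(manifest)
    if not labeled_cases:
        raise ValueError("training requires at least one densely labeled case")
    pair = NetworkPair(LMVSNet(cfg.net_config, cfg.seed_net1),
                       LMVSNet(cfg.net_config, cfg.seed_net2))
    opt1 = SGD(pair.net1.parameters(), cfg.lr0, cfg.momentum, cfg.weight_decay)
    opt2 = SGD(pair.net2.parameters(), cfg.lr0, cfg.momentum, cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed_data)
    sampler_l = _Sampler(labeled_cases, cfg, rng)
    sampler_u = _Sampler(unlabeled_cases, cfg, rng) if unlabeled_cases else None

    log = []
    for t in range(1, cfg.total_iters + 1):
        lr = poly_lr(cfg.lr0, t - 1, cfg.total_iters, cfg.poly_power)
        opt1.lr = opt2.lr = lr
        batch_l = sampler_l.sample(cfg.labeled_batch, labeled=True)
        batch_u = (sampler_u.sample(cfg.unlabeled_batch, labeled=False)
                   if sampler_u is not None and cfg.unlabeled_batch > 0 else None)
        parts = training_step(pair, batch_l, batch_u, t, cfg, opt1, opt2)
        parts["iteration"] = t
        parts["lr"] = lr
        log.append(parts)

    checkpoint_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        checkpoint_path = save_checkpoint(pair, cfg, out_dir / "checkpoint.npz")
        with (out_dir / "training_log.csv").open("w") as fh:
            fh.write(",".join(LOG_COLUMNS) + "\n")
            for row in log:
                fh.write(",".join(str(row[c]) for c in LOG_COLUMNS) + "\n")
    return TrainResult(pair, log, checkpoint_path)


def predict_volume(net: LMVSNet, vol: Volume, cfg: TrainConfig):
    """Sliding-window inference: stitch per-patch softmax by averaging,
    then binarize by argmax.  Returns (probability volume, binary mask)."""
    values = np.asarray(vol.values, dtype=np.float32)
    iso = (cfg.target_spacing,) * 3
    if any(abs(s - t) > 1e-6 for s, t in zip(vol.spacing, iso)):
        warnings.warn(f"volume spacing {vol.spacing} differs from training "
                      f"spacing {iso}; resampling", stacklevel=2)
        vol = resample_isotropic(vol, cfg.target_spacing, "linear")
        values = np.asarray(vol.values, dtype=np.float32)
    padded, pad = pad_to_min(values, cfg.patch_size)
    grid = plan_patch_grid(padded.shape, cfg.patch_size, cfg.stride)
    net.eval()
    prob_patches = []
    for pos in grid.positions:
        block = extract_patch(padded, pos, cfg.patch_size)
        out = net(block[None, None])
        prob_patches.append(out.data[0, 1])
    net.train()
    prob = stitch_probabilities(prob_patches, grid, padded.shape)
    prob = unpad(prob, pad)
    return prob, (prob > 0.5).astype(np.uint8)


def save_checkpoint(pair: NetworkPair, cfg: TrainConfig, path) -> Path:
    path = Path(path)
    arrays = {}
    for tag, net in (("net1", pair.net1), ("net2", pair.net2)):
        for i, arr in enumerate(net.state_arrays()):
            arrays[f"{tag}_{i:04d}"] = arr
    meta = {"net_config": dataclasses.asdict(cfg.net_config),
            "seeds": [cfg.seed_net1, cfg.seed_net2, cfg.seed_data],
            "patch_size": list(cfg.patch_size), "stride": list(cfg.stride)}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path) -> tuple:
    """Rebuild the trained pair from a checkpoint; returns (pair, meta)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        nc = meta["net_config"]
        nc["encoder_channels"] = tuple(nc["encoder_channels"])
        config = NetConfig(**nc)
        s1, s2, _ = meta["seeds"]
        pair = NetworkPair(LMVSNet(config, s1), LMVSNet(config, s2))
        for tag, net in (("net1", pair.net1), ("net2", pair.net2)):
            keys = sorted(k for k in data.files if k.startswith(tag))
            net.load_state_arrays([data[k] for k in keys])
    return pair, meta
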