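"""Scaled-down phantom benchmark for the co-training method.

The benchmark mirrors the study design — a few densely labeled training
volumes, a larger pool of unlabeled volumes, sparsely labeled test cases —
at desk scale: 32x32x16 voxel phantoms with two tubes each, a tiny
multi-view network, whole-volume patches and a few hundred iterations, so
a complete semi-supervised vs supervised-only comparison runs on one CPU
in minutes.  Problem sizes here are fixed once and shared by the tests,
the examples and the acceptance script.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .metrics import evaluate_sparse_case
from .model import NetConfig
from .patching import CutoutParams
from .phantom import DatasetManifest, PhantomSpec, make_dataset
from .trainer import TrainConfig, predict_volume, train
from .volume_io import read_label_volume, read_volume

__all__ = ["benchmark_phantom_spec", "tiny_net_config", "benchmark_config",
           "evaluate_on_test_cases", "run_condition", "BenchmarkResult",
           "run_phantom_benchmark"]


def benchmark_phantom_spec() -> PhantomSpec:
    """Small folded-tube phantoms: 24x24x12 voxels, two thin tubes."""
    return PhantomSpec(grid_shape=(24, 24, 12), n_tubes=2,
                       radius_range=(1.5, 2.5), contact_probability=0.25)


def tiny_net_config() -> NetConfig:
    """Two-level multi-view net, wide enough to train stably on one CPU."""
    return NetConfig(encoder_channels=(8, 16), bottleneck_channels=16)


def benchmark_config(total_iters: int = 150, seed_net1: int = 1,
                     seed_net2: int = 2, seed_data: int = 0,
                     semi_supervised: bool = True,
                     alpha: float = 0.5) -> TrainConfig:
    """Whole-volume patches, batch 2 + 2, reduced skeleton depth."""
    return TrainConfig(
        labeled_batch=2, unlabeled_batch=2, total_iters=total_iters,
        lr0=0.05, seed_net1=seed_net1, seed_net2=seed_net2,
        seed_data=seed_data, alpha=alpha, skeleton_iters=3,
        patch_size=(24, 24, 12), stride=(24, 24, 12),
        cutout=CutoutParams(prob=0.25),
        unsupervised_weight_scale=1.0 if semi_supervised else 0.0,
        net_config=tiny_net_config())


def evaluate_on_test_cases(net, manifest: DatasetManifest,
                           cfg: TrainConfig) -> float:
    """Mean test Dice (%) over the manifest's sparse test cases."""
    dices = []
    for case in manifest.select(annotation="sparse", split="test"):
        vol = read_volume(case.image_path)
        gt = read_label_volume(case.label_path, case.labeled_slice_indices)
        _, seg = predict_volume(net, vol, cfg)
        cm = evaluate_sparse_case(case.case_id, seg, gt)
        if not np.isnan(cm.dice):
            dices.append(cm.dice)
    return float(np.mean(dices))


def run_condition(manifest: DatasetManifest, cfg: TrainConfig) -> float:
    """Train one network pair and return its mean test Dice (net 1)."""
    result = train(cfg, manifest)
    return evaluate_on_test_cases(result.pair.net1, manifest, cfg)


@dataclasses.dataclass
class BenchmarkResult:
    dice_semi: list       # per data seed, mean test Dice (%) with co-training
    dice_supervised: list  # same seeds, supervised-only (gamma scale 0)

    @property
    def mean_semi(self) -> float:
        return float(np.mean(self.dice_semi))

    @property
    def mean_supervised(self) -> float:
        return float(np.mean(self.dice_supervised))


def run_phantom_benchmark(work_dir, data_seeds=(11, 12, 13),
                          n_labeled: int = 2, n_unlabeled: int = 10,
                          n_test: int = 4,
                          total_iters: int = 150) -> BenchmarkResult:
    """Semi-supervised benefit study on phantom data.

    For each data seed a fresh dataset (n_labeled dense + n_unlabeled
    unlabeled training volumes, n_test sparse test volumes) is generated,
    and the same network pair is trained twice: with bidirectional teaching
    and supervised-only (unsupervised weight zeroed).
    """
    work_dir = Path(work_dir)
    spec = benchmark_phantom_spec()
    semi_scores, sup_scores = [], []
    for i, seed in enumerate(data_seeds):
        ds_dir = work_dir / f"seed_{seed}"
        manifest = make_dataset(n_labeled, n_unlabeled, n_test, spec,
                                seed=seed, out_dir=ds_dir)
        for semi in (True, False):
            cfg = benchmark_config(total_iters=total_iters,
                                   seed_net1=2 * i + 1, seed_net2=2 * i + 2,
                                   seed_data=seed, semi_supervised=semi)
            score = run_condition(manifest, cfg)
            (semi_scores if semi else sup_scores).append(score)
    return BenchmarkResult(semi_scores, sup_scores)
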