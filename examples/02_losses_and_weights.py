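"""Tour of the loss components used for co-training.

Evaluates the gamma ramp at a few milestones, the distance weight of two
pseudo-labels (one boundary-heavy, one compact) and the Dice / clDice
blend on a toy tube.
"""

import numpy as np

from lumenseg import (SupervisedLossConfig, distance_weight, ramp_gamma,
                      soft_cl_dice_loss, soft_dice_loss, supervised_loss)
from lumenseg.nn import Tensor

T = 30_000
print("gamma ramp (weights the unsupervised loss over training):")
for t in (0, T // 2, T):
    print(f"  t = {t:6d}/{T}: gamma = {ramp_gamma(t, T):.6f}")

# A compact blob keeps voxels far from the background -> high weight;
# a thin scattered pseudo-label is boundary-dominated -> low weight.
blob = np.zeros((16, 16, 8), dtype=np.uint8)
blob[4:12, 4:12, 2:6] = 1
thin = np.zeros((16, 16, 8), dtype=np.uint8)
thin[::4, ::4, ::4] = 1
print(f"\ndistance weight, compact pseudo-label:   {distance_weight(blob).weight:.4f}")
print(f"distance weight, scattered pseudo-label: {distance_weight(thin).weight:.4f}")

# Dice vs centerline-Dice on a half-covered tube
g = np.zeros((14, 3, 3), dtype=np.float32)
g[2:12, 1, 1] = 1.0
p = np.zeros_like(g)
p[2:7, 1, 1] = 1.0
cfg = SupervisedLossConfig(alpha=0.5, skeleton_iters=2)
print(f"\nhalf-covered thin tube: Dice loss   = "
      f"{float(soft_dice_loss(Tensor(p), g).data):.4f}")
print(f"                        clDice loss = "
      f"{float(soft_cl_dice_loss(Tensor(p), g, 2).data):.4f}")
print(f"                        blended (alpha=0.5) = "
      f"{float(supervised_loss(Tensor(p), g, cfg).data):.4f}")
# clDice penalizes the missing half of the centerline (loss 1/3) even
# though plain Dice also sees the missing volume; the blend balances
# volumetric overlap against centerline coverage.
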