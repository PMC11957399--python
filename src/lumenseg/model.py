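"""Segmentation networks.

``LMVSNet`` is a lightweight multi-view symmetric encoder–decoder: each
encoder/decoder stage is a multi-view block whose four parallel branches
see effective receptive fields of 1, 3, 5 and 7 voxels per axis — the 5-
and 7-extents realized by stacking two and three 3x3x3 kernels, which is
far cheaper than literal 5x5x5 / 7x7x7 kernels (2*27*C^2 and 3*27*C^2
weights versus 125*C^2 and 343*C^2 at width C).  1x1x1 convolutions
reduce channels before each branch and fuse the concatenated branches.

``UNet3D`` is the classical two-convolutions-per-level 3-D U-Net baseline
with the original channel plan (encoder 32-64, 64-128, 128-256, bottom
256-512, mirrored decoder with 2x2x2 up-convolutions), whose trainable
parameter count rounds to 19 million.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import (BatchNorm3d, Conv3d, ConvTranspose3d, Module, Sequential,
                 Tensor, Upsample, concat, maxpool3d, relu, softmax_channel)

__all__ = ["NetConfig", "MultiViewBlock", "LMVSNet", "UNet3D",
           "build_lmvsnet", "build_unet3d_baseline", "count_parameters",
           "receptive_field_extent", "visualize_feature_maps"]


@dataclasses.dataclass
class NetConfig:
    """Architecture hyper-parameters of the multi-view network.

    Encoder widths must be strictly increasing; depth is their count.  The
    default widths with a 512-wide bottleneck give roughly 12.5M trainable
    parameters — well under the 19M of the 3-D U-Net baseline.
    """

    in_channels: int = 1
    n_classes: int = 2
    encoder_channels: tuple = (64, 128, 256, 512)
    bottleneck_channels: int = 512

    def validate(self) -> None:
        if self.n_classes != 2:
            raise ValueError("this task is two-class (background / lumen)")
        if len(self.encoder_channels) < 2:
            raise ValueError("depth must be >= 2")
        widths = tuple(self.encoder_channels)
        if any(b <= a for a, b in zip(widths, widths[1:])):
            raise ValueError("encoder widths must be strictly increasing")
        if self.in_channels < 1 or self.bottleneck_channels < widths[-1]:
            raise ValueError("invalid channel configuration")

    @property
    def depth(self) -> int:
        return len(self.encoder_channels)


class _ConvBNReLU(Module):
    def __init__(self, in_ch, out_ch, kernel, rng):
        super().__init__()
        self.conv = Conv3d(in_ch, out_ch, kernel, rng)
        self.bn = BatchNorm3d(out_ch)

    def forward(self, x):
        return relu(self.bn(self.conv(x)))


class MultiViewBlock(Module):
    """Four parallel receptive-field branches fused by a 1x1x1 convolution.

    Branch (a) is a pure 1x1x1 channel mix; branches (b), (c), (d) stack
    one, two and three 3x3x3 kernels after a 1x1x1 reduction, giving
    effective extents 3, 5 and 7.  ``out_ch`` is split equally across the
    branches (any remainder goes to branch (b)); every convolution is
    followed by batch normalization and ReLU; spatial shape is preserved.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        if min(in_ch, out_ch) < 1:
            raise ValueError("channel widths must be >= 1")
        base = max(1, out_ch // 4)
        widths = [base, base + max(0, out_ch - 4 * base), base, base]
        self.branches = []
        for n_stacked, w in zip((0, 1, 2, 3), widths):
            layers = [_ConvBNReLU(in_ch, w, 1, rng)]
            layers += [_ConvBNReLU(w, w, 3, rng) for _ in range(n_stacked)]
            self.branches.append(Sequential(*layers))
        self.fuse = _ConvBNReLU(sum(widths), out_ch, 1, rng)

    def forward(self, x):
        return self.fuse(concat([b(x) for b in self.branches], axis=1))


def _pool_factors(shape3):
    """Per-axis pool factor: 2 where the extent is even, 1 where it is 1."""
    factors = []
    for n in shape3:
        if n == 1:
            factors.append(1)
        elif n % 2 == 0:
            factors.append(2)
        else:
            raise ValueError(
                f"spatial extent {n} is odd and > 1; pad the input so every "
                f"axis is a power-of-two multiple at each downsampling level")
    return tuple(factors)


class _UpStage(Module):
    """Trilinear upsample by the recorded factors, then a 1x1x1 channel mix."""

    def __init__(self, in_ch, out_ch, rng):
        super().__init__()
        self.up = Upsample()
        self.mix = _ConvBNReLU(in_ch, out_ch, 1, rng)

    def forward(self, x, factors):
        self.up.factors = factors
        return self.mix(self.up(x))


class LMVSNet(Module):
    """Symmetric multi-view encoder–decoder with softmax two-class output."""

    def __init__(self, config: NetConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or NetConfig()
        self.config.validate()
        rng = np.random.default_rng(seed)
        self.seed = seed
        cfg = self.config
        widths = tuple(cfg.encoder_channels)
        self.encoder = []
        in_ch = cfg.in_channels
        for w in widths:
            self.encoder.append(MultiViewBlock(in_ch, w, rng))
            in_ch = w
        self.bottleneck = MultiViewBlock(widths[-1], cfg.bottleneck_channels, rng)
        self.upstages, self.decoder = [], []
        in_ch = cfg.bottleneck_channels
        for w in reversed(widths):
            self.upstages.append(_UpStage(in_ch, in_ch, rng))
            self.decoder.append(MultiViewBlock(in_ch + w, w, rng))
            in_ch = w
        self.head = Conv3d(widths[0], cfg.n_classes, 1, rng)

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        skips, factors = [], []
        for block in self.encoder:
            x = block(x)
            skips.append(x)
            f = _pool_factors(x.shape[2:])
            factors.append(f)
            x = maxpool3d(x, f)
        x = self.bottleneck(x)
        for up, block, skip, f in zip(self.upstages, self.decoder,
                                      reversed(skips), reversed(factors)):
            x = up.forward(x, f)
            x = block(concat([skip, x], axis=1))
        return softmax_channel(self.head(x))


class UNet3D(Module):
    """Original two-convolutions-per-level 3-D U-Net (19M-parameter plan)."""

    PLAN = ((32, 64), (64, 128), (128, 256), (256, 512))

    def __init__(self, seed: int = 0, n_classes: int = 2):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.seed = seed
        self.enc = []
        in_ch = 1
        for a, b in self.PLAN:
            self.enc.append(Sequential(_ConvBNReLU(in_ch, a, 3, rng),
                                       _ConvBNReLU(a, b, 3, rng)))
            in_ch = b
        self.ups, self.dec = [], []
        for (a, b) in reversed(self.PLAN[:-1]):
            self.ups.append(ConvTranspose3d(in_ch, in_ch, rng))
            self.dec.append(Sequential(_ConvBNReLU(in_ch + b, b, 3, rng),
                                       _ConvBNReLU(b, b, 3, rng)))
            in_ch = b
        self.head = Conv3d(in_ch, n_classes, 1, rng)

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        skips = []
        for i, level in enumerate(self.enc):
            x = level(x)
            if i < len(self.enc) - 1:
                skips.append(x)
                x = maxpool3d(x, (2, 2, 2))
        for up, level, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up(x)
            x = level(concat([skip, x], axis=1))
        return softmax_channel(self.head(x))


def build_lmvsnet(config: NetConfig | None = None, seed: int = 0) -> LMVSNet:
    return LMVSNet(config, seed)


def build_unet3d_baseline(seed: int = 0) -> UNet3D:
    return UNet3D(seed)


def count_parameters(net: Module) -> int:
    """Exact count of trainable scalars (frozen parameters excluded)."""
    return int(sum(p.data.size for p in net.parameters() if p.requires_grad))


def receptive_field_extent(n_stacked: int) -> int:
    """Extent (voxels per axis) of n stacked stride-1 3x3x3 convolutions."""
    if n_stacked < 1:
        raise ValueError("n_stacked must be >= 1")
    return 2 * n_stacked + 1


def visualize_feature_maps(features: np.ndarray) -> np.ndarray:
    """Render a feature block as a 2-D blue-to-red color image.

    The channel mean is taken first, then (for 3-D blocks) the middle
    axial slice, min–max scaled to integers 0–255 and mapped through a
    blue-to-red colormap.  A constant input maps to the low (blue) end.
    Returns a uint8 RGB image.
    """
    feats = np.asarray(features, dtype=np.float32)
    if feats.size == 0:
        raise ValueError("features must be non-empty")
    if feats.ndim < 3:
        raise ValueError("expected (channels, ...spatial) features")
    mean = feats.mean(axis=0)
    if mean.ndim == 3:
        mean = mean[:, :, mean.shape[2] // 2]
    mn, mx = float(mean.min()), float(mean.max())
    if mx > mn:
        gray = np.rint((mean - mn) / (mx - mn) * 255.0).astype(np.uint8)
    else:
        gray = np.zeros(mean.shape, dtype=np.uint8)
    from matplotlib import colormaps
    rgba = colormaps["jet"](gray / 255.0)
    return np.rint(rgba[..., :3] * 255.0).astype(np.uint8)
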