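# Methods

## Problem setting and model

The package segments tubular lumen structures (small/large bowel lumen)
from 3-D CT-like volumes under weak supervision: a few densely labeled
training volumes, a large unlabeled pool, and test volumes annotated on a
small subset of axial slices (1.00–5.31 % of slices by default).  Volumes
are resampled to 1 mm isotropic spacing before training; the resampled
grid size per axis is `round_half_away(n · spacing / 1 mm)`, which is the
rounding rule consistent with the documented resampling bounds
(512 px at 0.549 mm → 281 px; 512 at 0.904 → 463; 198 slices at 2 mm →
396).  Intensities are optionally windowed (default −1000…400 HU, spanning
air-filled lumen through soft tissue) and mapped affinely to [0, 1].

Two networks `f1, f2` with identical architecture and different seeds are
co-trained.  Per iteration a labeled and an unlabeled patch batch are fed
to both networks.  Supervision is

    L_sup = α·L_Dice + (1−α)·L_clDice,            α = 0.5

where the clDice term compares soft morphological skeletons: topology
precision (prediction skeleton inside ground truth) and topology
sensitivity (ground-truth skeleton recovered by the prediction), combined
as a harmonic mean.  The soft skeleton alternates separable soft erosion
(axis-wise 3-window min) with soft opening, accumulating ridge residuals
for `k` iterations; `k` must reach the tube radius (default 5 for
full-size data, 3 in the scaled benchmark where radii are ≤ 2.5 voxels).
The ground-truth skeleton is a constant and is computed by a gradient-free
mirror of the same routine.

Each network's unlabeled prediction is scored against the *other*
network's argmax pseudo-label (ties assigned to background), weighted by
that pseudo-label's distance weight: the Euclidean distance transform of
the pseudo-label, min–max normalized per patch, averaged to a scalar
`w ∈ [0, 1]`.  Since the Dice loss is a per-patch scalar, the voxel-wise
weighted sum in the definition reduces exactly to `L_Dice · w`; both forms
agree in the tests.  Degenerate conventions: an all-background
pseudo-label gets weight 0 (nothing trustworthy to teach), an
all-foreground one weight 1 (pure interior).  Pseudo-labels and distance
maps are gradient-detached, so a network is never differentiated through
its teacher; the tests verify this both by inspecting the autodiff graph
and by finite differences (the argmax is locally constant).

The total loss sums the two supervised terms and the two cross terms
scaled by `γ(t) = 0.1·e^{−5(1−t/T)}`, strictly increasing from
0.1·e⁻⁵ ≈ 6.74·10⁻⁴ to 0.1 at the final iteration.

## Architecture

Multi-view blocks have four parallel branches with receptive extents 1,
3, 5 and 7 voxels per axis; the 5- and 7-extents stack two and three
3×3×3 convolutions (the stacks do not share stages).  A 1×1×1 convolution
reduces channels ahead of each branch; the concatenated branches are fused
by another 1×1×1.  Every convolution is followed by batch normalization
and ReLU.  The output width splits equally over the four branches, any
remainder going to the single-3×3×3 branch.  The encoder applies a block
then 2×2×2 max pooling per level (an axis of extent 1 is not pooled; an
odd extent > 1 is rejected with the required padding reported), a
bottleneck block, and a mirrored decoder of trilinear upsampling + 1×1×1
mix, skip concatenation and a block, ending in a 1×1×1 two-class head with
channel softmax.

Default widths are (64, 128, 256, 512) with a 512-wide bottleneck,
≈ 12.5 M trainable parameters.  Narrower widths of (32, 64, 128, 256)
were considered but compute to only ≈ 3.6 M parameters, far below the
intended "lightweight but comparable" budget relative to the ≈ 19 M 3-D
U-Net baseline, so the wider plan was adopted; widths remain fully
configurable.  The baseline U-Net follows the original recipe exactly
(two 3×3×3 convolutions per level, encoder 32→64, 64→128, 128→256, bottom
256→512, 2×2×2 up-convolutions, mirrored decoder), giving 19,073,730
trainable scalars.

## Training

SGD with momentum 0.9 and weight decay 10⁻⁴ (standard values; the source
recipe leaves them unstated), initial learning rate 0.01 with the poly
schedule `lr(t) = lr₀(1 − t/T)^0.9`, 30,000 iterations and batch 8 + 8
(labeled + unlabeled patches) by default; the final-iteration model is
kept, with no validation-based selection.  Patches are 256×256×16 voxels
on a 128×128×8 stride; smaller volumes are symmetrically zero-padded.  The
last window per axis is clamped to end at the volume border so every patch
contains real data.  Augmentation: independent per-axis flips (p = 0.5,
label transformed identically) and cut-out (p = 0.5, one cuboid with edges
10–25 % of the patch, image set to 0, label untouched) — the cut-out
recipe is a 3-D adaptation of the published 2-D scheme, whose parameters
are unstated.  Labeled sampling draws a foreground-containing grid
position with probability 0.5 to counter class imbalance.  Inference uses
network 1 by default (the reference method does not say which co-trained
network is reported); a flag averages both.  The supervised loss is pooled
over the batch block (batch Dice/clDice); the unsupervised term is
evaluated per patch, matching its per-patch weight definition.

All optimization runs on the package's own NumPy reverse-mode autodiff
core (`lumenseg.nn`): stride-1 "same" 3-D convolution via im2col/einsum
with the input gradient expressed as a correlation with the flipped
kernel, kernel-2 stride-2 transposed convolution, block max pooling,
fused batch normalization, trilinear upsampling as per-axis linear maps,
and edge-clamped shifts for the soft morphology.  Every operator's
gradient is tested against central finite differences.

## Synthetic phantoms

A phantom is a set of tubes on a noisy background: each centerline is a
unit-step 3-D random walk whose per-step turn is bounded to 30°, reflected
at the grid margins, smoothed by a moving average, rasterized, and
inflated by thresholding the Euclidean distance transform at a radius
drawn from `radius_range`.  With probability `contact_probability` a tube
starts within 2 voxels of an existing centerline, creating touching
lumens.  The lumen renders darker than the background (air-like) by
default — contrast is a free parameter, not a claim of CT realism — with
additive Gaussian noise (σ = 0.05 in normalized units).  Defaults
(96×96×32 voxels, 3 tubes, radii 2–4) give foreground fractions of a few
percent, comparable to bowel lumen in abdominal CT.  Sparse test labels
keep `round(fraction · Z)` axial slices (at least one), with fractions
drawn from [0.0100, 0.0531].  Identical (spec, seed) pairs are
bit-identical.  What the phantoms do *not* emulate: CT physics (beam
hardening, partial volume), anatomy (wall thickness, haustra, adjacent
organs), pathology, or realistic intensity statistics — so passing tests
demonstrate the correctness and the learning dynamics of the machinery,
not clinical accuracy.

## Scaled benchmark

The semi-supervised benchmark mirrors the study design at desk scale:
24×24×12-voxel phantoms (2 tubes, radii 1.5–2.5), 2 densely labeled + 10
unlabeled training volumes, 4 sparsely labeled test volumes, three data
seeds, and for each seed one network pair trained twice — bidirectional
teaching versus supervised-only (cross term zeroed) — with whole-volume
patches, batch 2 + 2, a two-level multi-view net of widths (8, 16), lr₀
0.05 and 150 iterations.  The network width and learning rate were set
during benchmark design because very narrow nets (branch widths of one
channel) intermittently saturate into an all-foreground basin at this
scale; the (8, 16) configuration trains stably in both arms.  Evaluation
follows the sparse-slice protocol on network 1.  The expected property is
a mean-test-Dice advantage (or tie) for bidirectional teaching across
seeds, not a fixed margin.

## Evaluation conventions

Per-case confusion counts are pooled over the labeled slices, then
converted to Dice/precision/recall (×100); a metric with a zero
denominator is NaN and the case is excluded from that metric's average.
NSD extracts 6-connectivity boundary voxels (volume-border voxels count as
surface) and reports the fraction of the two surfaces within 3.0 mm of
each other, distances in mm via the voxel spacing.  For sparse cases NSD
is computed on the sub-volume formed by gathering the labeled slices — an
approximation, since surface geometry across unlabeled slices is unknown.
Repeated runs aggregate as the mean over cases within a run, then mean and
*population* SD across runs (the SD convention is a documented choice).

## Known limitations

Pure-NumPy training is orders of magnitude slower than GPU frameworks, so
full-scale runs (30 k iterations on 256×256×16 patches) are impractical
here; all shipped experiments use the scaled benchmark.  Batch
normalization statistics are computed over the concatenated
labeled+unlabeled batch; very small batches make them noisy.  The
translation-equivariance of the networks holds only on interior voxels
because of zero padding.  The phantom benchmark's effect sizes are small
(both arms reach high Dice), so the semi-supervised comparison is a
robustness check rather than a replication of clinical-scale gains.
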