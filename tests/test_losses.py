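"""Loss terms: hand-computed values, oracle equivalences, reductions."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import skeletonize

from lumenseg import (DistanceWeightMap, SupervisedLossConfig,
                      distance_weight, ramp_gamma, soft_cl_dice_loss,
                      soft_dice_loss, soft_skeleton, supervised_loss,
                      total_loss, unsupervised_loss)
from lumenseg.losses import soft_skeleton_np
from lumenseg.nn import Tensor


# ---------------------------------------------------------------- soft Dice
def test_dice_loss_zero_for_perfect_prediction(rng):
    g = (rng.uniform(size=(6, 6, 6)) > 0.6).astype(np.float32)
    assert float(soft_dice_loss(Tensor(g), g).data) < 1e-4


def test_dice_loss_hand_value_for_uniform_half_probability():
    g = np.zeros((2, 2, 2), dtype=np.float32)
    g.ravel()[:4] = 1.0
    prob = np.full((2, 2, 2), 0.5, dtype=np.float32)
    # 1 - 2*(0.5*4)/(0.5*8 + 4) = 0.5
    assert float(soft_dice_loss(Tensor(prob), g).data) == pytest.approx(0.5, abs=1e-4)


def test_dice_loss_near_one_for_disjoint_masks():
    p = np.zeros((4, 4, 4), dtype=np.float32)
    g = np.zeros((4, 4, 4), dtype=np.float32)
    p[0, 0, 0] = 1.0
    g[3, 3, 3] = 1.0
    assert float(soft_dice_loss(Tensor(p), g).data) > 0.999


def test_dice_loss_rejects_shape_mismatch():
    with pytest.raises(ValueError):
        soft_dice_loss(Tensor(np.zeros((2, 2, 2))), np.zeros((2, 2, 3)))


# ------------------------------------------------------------ soft skeleton
def test_skeleton_of_thin_line_is_the_line():
    line = np.zeros((1, 1, 9, 3, 3), dtype=np.float32)
    line[0, 0, :, 1, 1] = 1.0
    skel = soft_skeleton(Tensor(line), k=3).data
    assert np.array_equal(skel, line)


def test_skeleton_of_empty_volume_is_empty():
    z = np.zeros((1, 1, 4, 4, 4), dtype=np.float32)
    assert soft_skeleton(Tensor(z), k=2).data.sum() == 0


def test_skeleton_of_solid_tube_concentrates_on_medial_axis():
    """Soft skeleton support of a radius-5 tube stays within one voxel of
    the hard morphological skeleton."""
    shape = (24, 13, 13)
    tube = np.zeros(shape, dtype=np.float32)
    xx, yy = np.meshgrid(np.arange(13), np.arange(13), indexing="ij")
    disc = (xx - 6) ** 2 + (yy - 6) ** 2 <= 5 ** 2
    tube[:, disc] = 1.0
    soft = soft_skeleton(Tensor(tube[None, None]), k=5).data[0, 0]
    support = np.argwhere(soft > 0.5)
    assert len(support)
    hard = skeletonize(tube.astype(bool))
    dist_to_hard = ndimage.distance_transform_edt(~hard)
    # ignore tube end caps where both skeletons are edge-distorted
    core = support[(support[:, 0] > 5) & (support[:, 0] < 18)]
    assert dist_to_hard[tuple(core.T)].max() <= 1.0


def test_soft_skeleton_np_mirrors_autodiff_version(rng):
    x = rng.uniform(size=(1, 1, 6, 6, 6)).astype(np.float32)
    assert np.allclose(soft_skeleton(Tensor(x), 3).data,
                       soft_skeleton_np(x, 3), atol=1e-6)


# ------------------------------------------------------------------- clDice
def test_cl_dice_zero_for_exact_thin_tube():
    line = np.zeros((9, 3, 3), dtype=np.float32)
    line[:, 1, 1] = 1.0
    loss = soft_cl_dice_loss(Tensor(line), line, k=3)
    assert float(loss.data) < 1e-3


def test_cl_dice_hand_value_for_half_covered_line():
    """A 5-voxel prediction on a 10-voxel line: clDice = 2/3, loss = 1/3."""
    g = np.zeros((14, 3, 3), dtype=np.float32)
    g[2:12, 1, 1] = 1.0
    p = np.zeros_like(g)
    p[2:7, 1, 1] = 1.0
    loss = soft_cl_dice_loss(Tensor(p), g, k=2)
    assert float(loss.data) == pytest.approx(1.0 / 3.0, abs=5e-3)


def test_cl_dice_near_one_for_empty_prediction():
    g = np.zeros((8, 3, 3), dtype=np.float32)
    g[:, 1, 1] = 1.0
    loss = soft_cl_dice_loss(Tensor(np.zeros_like(g)), g, k=2)
    assert float(loss.data) > 0.99


# -------------------------------------------------------- supervised blend
def test_supervised_loss_alpha_reductions(rng):
    p = rng.uniform(size=(6, 6, 6)).astype(np.float32)
    g = (rng.uniform(size=(6, 6, 6)) > 0.6).astype(np.float32)
    dice = float(soft_dice_loss(Tensor(p), g).data)
    cl = float(soft_cl_dice_loss(Tensor(p), g, k=3).data)
    assert float(supervised_loss(Tensor(p), g,
                                 SupervisedLossConfig(1.0, 1e-5, 3)).data) \
        == pytest.approx(dice, abs=1e-6)
    assert float(supervised_loss(Tensor(p), g,
                                 SupervisedLossConfig(0.0, 1e-5, 3)).data) \
        == pytest.approx(cl, abs=1e-6)
    blended = float(supervised_loss(Tensor(p), g,
                                    SupervisedLossConfig(0.5, 1e-5, 3)).data)
    assert blended == pytest.approx(0.5 * dice + 0.5 * cl, abs=1e-6)


# --------------------------------------------------------- distance weight
def test_distance_weight_empty_pseudo_label():
    dw = distance_weight(np.zeros((4, 4, 4), dtype=np.uint8))
    assert dw.weight == 0.0
    assert dw.values.sum() == 0


def test_distance_weight_single_voxel():
    pseudo = np.zeros((4, 4, 4), dtype=np.uint8)
    pseudo[1, 2, 3] = 1
    dw = distance_weight(pseudo)
    assert dw.values[1, 2, 3] == 1.0
    assert dw.values.sum() == 1.0
    assert dw.weight == pytest.approx(1 / 64)


def test_distance_weight_all_foreground_convention():
    dw = distance_weight(np.ones((3, 3, 3), dtype=np.uint8))
    assert dw.weight == 1.0
    assert np.all(dw.values == 1.0)


def test_distance_weight_matches_brute_force_search(rng):
    """Per-voxel nearest-background Euclidean search on small grids."""
    for _ in range(3):
        pseudo = (rng.uniform(size=(6, 6, 6)) > 0.5).astype(np.uint8)
        if pseudo.sum() in (0, pseudo.size):
            continue
        dw = distance_weight(pseudo)
        bg = np.argwhere(pseudo == 0)
        raw = np.zeros(pseudo.shape)
        for idx in np.argwhere(pseudo == 1):
            raw[tuple(idx)] = np.sqrt(((bg - idx) ** 2).sum(axis=1).min())
        norm = (raw - raw.min()) / (raw.max() - raw.min())
        assert np.allclose(dw.values, norm, atol=1e-5)
        assert dw.weight == pytest.approx(norm.mean(), abs=1e-6)


def test_distance_weight_rejects_nonbinary():
    with pytest.raises(ValueError):
        distance_weight(np.full((2, 2, 2), 0.5))


# ------------------------------------------------------- unsupervised loss
def test_unsupervised_loss_reduces_to_dice_for_unit_map(rng):
    p = rng.uniform(size=(4, 4, 4)).astype(np.float32)
    pseudo = (rng.uniform(size=(4, 4, 4)) > 0.5).astype(np.uint8)
    unit = DistanceWeightMap(np.ones((4, 4, 4), dtype=np.float32), 1.0)
    assert float(unsupervised_loss(Tensor(p), pseudo, unit).data) == \
        pytest.approx(float(soft_dice_loss(Tensor(p), pseudo).data), abs=1e-6)


def test_unsupervised_loss_vanishes_for_empty_pseudo_label(rng):
    p = rng.uniform(size=(4, 4, 4)).astype(np.float32)
    pseudo = np.zeros((4, 4, 4), dtype=np.uint8)
    assert float(unsupervised_loss(Tensor(p), pseudo,
                                   distance_weight(pseudo)).data) == 0.0


def test_unsupervised_loss_matches_direct_triple_sum(rng):
    """Direct evaluation of the voxel-wise weighted sum definition."""
    p = rng.uniform(size=(4, 4, 4)).astype(np.float32)
    pseudo = (rng.uniform(size=(4, 4, 4)) > 0.4).astype(np.uint8)
    dw = distance_weight(pseudo)
    val = float(unsupervised_loss(Tensor(p), pseudo, dw).data)
    dice = float(soft_dice_loss(Tensor(p), pseudo).data)
    direct = 0.0
    for x in range(4):
        for y in range(4):
            for z in range(4):
                direct += dice * dw.values[x, y, z]
    direct /= 64
    assert val == pytest.approx(direct, abs=1e-6)


def test_unsupervised_loss_rejects_mismatched_map(rng):
    pseudo = np.zeros((4, 4, 4), dtype=np.uint8)
    bad = DistanceWeightMap(np.zeros((2, 2, 2), dtype=np.float32), 0.0)
    with pytest.raises(ValueError):
        unsupervised_loss(Tensor(np.zeros((4, 4, 4))), pseudo, bad)


# -------------------------------------------------------------- gamma ramp
def test_gamma_ramp_printed_values():
    assert ramp_gamma(100, 100) == pytest.approx(0.1, abs=1e-12)
    assert ramp_gamma(0, 100) == pytest.approx(6.7379e-4, rel=1e-4)
    assert ramp_gamma(50, 100) == pytest.approx(8.2085e-3, rel=1e-4)


def test_gamma_ramp_strictly_increasing_and_bounded():
    ts = np.linspace(0, 1000, 21)
    vals = [ramp_gamma(t, 1000) for t in ts]
    assert all(a < b for a, b in zip(vals, vals[1:]))
    assert vals[0] >= 0.1 * np.exp(-5) - 1e-12
    assert vals[-1] <= 0.1


def test_gamma_ramp_rejects_bad_arguments():
    with pytest.raises(ValueError):
        ramp_gamma(1, 0)
    with pytest.raises(ValueError):
        ramp_gamma(5, 4)


# -------------------------------------------------------------- total loss
def _total_inputs(rng):
    shape = (4, 4, 4)
    g = (rng.uniform(size=shape) > 0.5).astype(np.uint8)
    probs = [rng.uniform(size=shape).astype(np.float32) for _ in range(4)]
    pseudos = [(rng.uniform(size=shape) > 0.5).astype(np.uint8) for _ in range(2)]
    dmaps = [distance_weight(ps) for ps in pseudos]
    return g, probs, pseudos, dmaps


def test_total_loss_equals_sum_of_independent_terms(rng):
    g, (p1l, p2l, p1u, p2u), (ps1, ps2), (d1, d2) = _total_inputs(rng)
    cfg = SupervisedLossConfig(0.5, 1e-5, 2)
    t, T = 30, 100
    loss, parts = total_loss(Tensor(p1l), Tensor(p2l), g, Tensor(p1u),
                             Tensor(p2u), ps1, ps2, d1, d2, t, T, cfg)
    gamma = ramp_gamma(t, T)
    expect = (float(supervised_loss(Tensor(p1l), g, cfg).data)
              + float(supervised_loss(Tensor(p2l), g, cfg).data)
              + gamma * float(unsupervised_loss(Tensor(p1u), ps2, d2).data)
              + gamma * float(unsupervised_loss(Tensor(p2u), ps1, d1).data))
    assert float(loss.data) == pytest.approx(expect, rel=1e-5)
    assert parts["gamma"] == gamma


def test_total_loss_symmetric_under_network_swap(rng):
    g, (p1l, p2l, p1u, p2u), (ps1, ps2), (d1, d2) = _total_inputs(rng)
    cfg = SupervisedLossConfig(0.5, 1e-5, 2)
    a, _ = total_loss(Tensor(p1l), Tensor(p2l), g, Tensor(p1u), Tensor(p2u),
                      ps1, ps2, d1, d2, 10, 100, cfg)
    b, _ = total_loss(Tensor(p2l), Tensor(p1l), g, Tensor(p2u), Tensor(p1u),
                      ps2, ps1, d2, d1, 10, 100, cfg)
    assert float(a.data) == pytest.approx(float(b.data), rel=1e-6)


def test_total_loss_reduces_to_supervised_for_tiny_gamma(rng):
    g, (p1l, p2l, p1u, p2u), (ps1, ps2), (d1, d2) = _total_inputs(rng)
    cfg = SupervisedLossConfig(0.5, 1e-5, 2)
    loss, parts = total_loss(Tensor(p1l), Tensor(p2l), g, Tensor(p1u),
                             Tensor(p2u), ps1, ps2, d1, d2, 0, 10**7, cfg)
    sup_sum = parts["l_sup1"] + parts["l_sup2"]
    assert float(loss.data) == pytest.approx(sup_sum, abs=2e-3)


def test_loss_terms_bounded(rng):
    """All individual terms live in [0, 1]; the total in [0, 2 + 2 gamma]."""
    for _ in range(3):
        g, (p1l, p2l, p1u, p2u), (ps1, ps2), (d1, d2) = _total_inputs(rng)
        cfg = SupervisedLossConfig(0.5, 1e-5, 2)
        loss, parts = total_loss(Tensor(p1l), Tensor(p2l), g, Tensor(p1u),
                                 Tensor(p2u), ps1, ps2, d1, d2, 50, 100, cfg)
        for key in ("l_sup1", "l_sup2", "l_un1", "l_un2"):
            assert 0.0 <= parts[key] <= 1.0
        assert 0.0 <= float(loss.data) <= 2.0 + 2.0 * parts["gamma"]
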