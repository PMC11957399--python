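"""Co-training mechanics: pseudo-labels, detachment, determinism, inference."""

import copy

import numpy as np
import pytest

from lumenseg import (LMVSNet, TrainConfig, Volume, make_dataset,
                      make_pseudo_label, predict_volume, train, training_step)
from lumenseg.benchmark import benchmark_config, benchmark_phantom_spec
from lumenseg.losses import distance_weight, soft_dice_loss
from lumenseg.nn import SGD, Tensor, poly_lr, take_index
from lumenseg.trainer import (NetworkPair, load_checkpoint, save_checkpoint)


# ------------------------------------------------------------ pseudo-labels
def test_pseudo_label_argmax_and_tie_break():
    prob = np.zeros((2, 1, 1, 3))
    prob[0, 0, 0] = [0.7, 0.2, 0.5]
    prob[1, 0, 0] = [0.3, 0.8, 0.5]
    out = make_pseudo_label(prob)
    assert out[0, 0, 0] == 0       # background wins
    assert out[0, 0, 1] == 1
    assert out[0, 0, 2] == 0       # exact tie -> background


def test_pseudo_label_matches_per_voxel_oracle(rng):
    fg = rng.uniform(size=(1, 4, 4, 4)).astype(np.float32)
    prob = np.stack([1 - fg, fg], axis=1)
    out = make_pseudo_label(prob)
    ref = np.zeros((1, 4, 4, 4), dtype=np.uint8)
    for idx in np.ndindex(*fg.shape):
        ref[idx] = 1 if fg[idx] > 1 - fg[idx] else 0
    assert np.array_equal(out, ref)
    assert set(np.unique(out)) <= {0, 1}


def test_pseudo_label_rejects_wrong_channel_count():
    with pytest.raises(ValueError):
        make_pseudo_label(np.zeros((1, 3, 2, 2, 2)))


# --------------------------------------------------------------- schedules
def test_poly_learning_rate_endpoints():
    assert poly_lr(0.01, 0, 30000) == pytest.approx(0.01)
    assert poly_lr(0.01, 30000, 30000, 0.9) == 0.0
    mid = poly_lr(0.01, 15000, 30000, 0.9)
    assert 0 < mid < 0.01


def _small_setup(tiny_net_config, rng, seed1=1, seed2=2):
    cfg = TrainConfig(labeled_batch=1, unlabeled_batch=1, total_iters=100,
                      seed_net1=seed1, seed_net2=seed2,
                      patch_size=(8, 8, 4), stride=(8, 8, 4),
                      skeleton_iters=2, net_config=tiny_net_config)
    imgs = rng.normal(size=(1, 1, 8, 8, 4)).astype(np.float32)
    labels = (rng.uniform(size=(1, 8, 8, 4)) > 0.7).astype(np.uint8)
    unlabeled = rng.normal(size=(1, 1, 8, 8, 4)).astype(np.float32)
    pair = NetworkPair(LMVSNet(tiny_net_config, seed1),
                       LMVSNet(tiny_net_config, seed2))
    return cfg, pair, imgs, labels, unlabeled


def test_zero_gamma_reproduces_supervised_only_updates(tiny_net_config, rng):
    cfg, pair_a, imgs, labels, unlabeled = _small_setup(tiny_net_config, rng)
    pair_b = copy.deepcopy(pair_a)
    cfg.unsupervised_weight_scale = 0.0
    opts_a = [SGD(net.parameters(), 0.01) for net in (pair_a.net1, pair_a.net2)]
    opts_b = [SGD(net.parameters(), 0.01) for net in (pair_b.net1, pair_b.net2)]
    training_step(pair_a, (imgs, labels), unlabeled, 50, cfg, *opts_a)
    training_step(pair_b, (imgs, labels), None, 50, cfg, *opts_b)
    for pa, pb in zip(pair_a.net1.parameters(), pair_b.net1.parameters()):
        assert np.array_equal(pa.data, pb.data)


def test_cross_term_carries_no_gradient_through_the_teacher(tiny_net_config, rng):
    """The pseudo-label/distance-map path from the teacher network is cut:
    the cross loss has zero analytic gradient w.r.t. the teacher, and its
    finite difference through argmax is zero for small perturbations."""
    _, pair, _, _, unlabeled = _small_setup(tiny_net_config, rng)
    x_u = Tensor(unlabeled)

    def cross_loss_value():
        p1_u = take_index(pair.net1(x_u), 1, 1)
        p2_u = pair.net2(x_u).data[:, 1]
        pseudo2 = make_pseudo_label(np.stack([1 - p2_u, p2_u], axis=1))[0]
        d2 = distance_weight(pseudo2)
        return soft_dice_loss(take_index(p1_u, 0, 0), pseudo2) * d2.weight

    loss = cross_loss_value()
    pair.net1.zero_grad()
    pair.net2.zero_grad()
    loss.backward()
    assert all(p.grad is None for p in pair.net2.parameters())
    assert any(p.grad is not None for p in pair.net1.parameters())
    # finite differences: perturbing the teacher leaves the loss unchanged
    base = float(loss.data)
    params = list(pair.net2.parameters())
    for p in params[:3]:
        orig = p.data.ravel()[0]
        p.data.ravel()[0] = orig + 1e-4
        assert float(cross_loss_value().data) == pytest.approx(base, abs=1e-6)
        p.data.ravel()[0] = orig


def test_identical_net_seeds_yield_identical_pseudo_labels(tiny_net_config, rng):
    _, pair, _, _, unlabeled = _small_setup(tiny_net_config, rng,
                                            seed1=3, seed2=3)
    p1 = pair.net1(unlabeled).data
    p2 = pair.net2(unlabeled).data
    assert np.array_equal(make_pseudo_label(p1), make_pseudo_label(p2))


def test_config_rejects_equal_network_seeds(tiny_net_config):
    cfg = TrainConfig(seed_net1=4, seed_net2=4, net_config=tiny_net_config)
    with pytest.raises(ValueError):
        cfg.validate()


def test_empty_labeled_batch_rejected(tiny_net_config, rng):
    cfg, pair, imgs, labels, _ = _small_setup(tiny_net_config, rng)
    with pytest.raises(ValueError):
        training_step(pair, (imgs[:0], labels[:0]), None, 1, cfg)


# ------------------------------------------------------------ training loop
@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("phantom_ds")
    return make_dataset(1, 1, 1, benchmark_phantom_spec(), seed=5, out_dir=out)


def test_training_is_reproducible_and_logs_the_ramp(tiny_dataset, tmp_path):
    cfg = benchmark_config(total_iters=12)
    res1 = train(cfg, tiny_dataset, out_dir=tmp_path / "run1")
    res2 = train(cfg, tiny_dataset)
    log1 = [r["l_total"] for r in res1.log]
    log2 = [r["l_total"] for r in res2.log]
    assert log1 == log2
    assert all(np.isfinite(log1))
    # gamma column reproduces the ramp exactly
    from lumenseg import ramp_gamma
    for row in res1.log:
        assert row["gamma"] == ramp_gamma(row["iteration"], cfg.total_iters)
    assert (tmp_path / "run1" / "training_log.csv").exists()

    # checkpoint round-trip preserves behavior
    pair, meta = load_checkpoint(res1.checkpoint_path)
    x = np.random.default_rng(0).normal(size=(1, 1, 8, 8, 4)).astype(np.float32)
    a = res1.pair.net1.eval()(x).data
    b = pair.net1.eval()(x).data
    assert np.array_equal(a, b)


def test_training_requires_labeled_cases(tiny_dataset, tmp_path):
    from lumenseg.phantom import DatasetManifest
    unl_only = DatasetManifest([c for c in tiny_dataset.cases
                                if c.annotation == "unlabeled"])
    with pytest.raises(ValueError):
        train(benchmark_config(total_iters=1), unl_only)


# --------------------------------------------------------------- inference
def test_constant_background_net_yields_empty_segmentation(tiny_net_config):
    net = LMVSNet(tiny_net_config, seed=0)
    net.head.weight.data[:] = 0.0
    net.head.bias.data[:] = [5.0, -5.0]   # class 0 (background) certain
    cfg = TrainConfig(patch_size=(8, 8, 4), stride=(4, 4, 2),
                      net_config=tiny_net_config)
    vol = Volume(np.random.default_rng(1).normal(size=(12, 12, 8))
                 .astype(np.float32))
    prob, seg = predict_volume(net, vol, cfg)
    assert seg.sum() == 0
    assert prob.max() < 0.01
    # constant-output net stitches to a constant probability volume
    assert np.allclose(prob, prob.ravel()[0], atol=1e-5)


def test_predict_resamples_on_spacing_mismatch(tiny_net_config):
    net = LMVSNet(tiny_net_config, seed=0)
    cfg = TrainConfig(patch_size=(8, 8, 4), stride=(8, 8, 4),
                      net_config=tiny_net_config)
    vol = Volume(np.zeros((8, 8, 4), dtype=np.float32), spacing=(2.0, 1.0, 1.0))
    with pytest.warns(UserWarning, match="resampl"):
        prob, seg = predict_volume(net, vol, cfg)
    assert prob.shape == (16, 8, 4)
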