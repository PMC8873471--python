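import math

import numpy as np
import pytest

from holodsn import nn
from holodsn.dsn_model import DSNModel, ExpertModel, mini_spec
from holodsn.preprocess import PatchPair
from holodsn.train import (
    Adam,
    TrainConfig,
    bce_loss,
    initialize,
    regularized_loss,
    train_model,
)


def test_bce_half_everywhere_is_ln2(rng):
    target = (rng.uniform(size=(4, 4, 4)) > 0.5).astype(float)
    loss = bce_loss(nn.constant(np.full((4, 4, 4), 0.5)), target)
    assert loss.item() == pytest.approx(math.log(2.0), abs=1e-12)


def test_bce_two_voxel_hand_computation():
    # y = (1, 0), p = (0.8, 0.3): -(ln 0.8 + ln 0.7) / 2 = 0.28990...
    loss = bce_loss(nn.constant(np.array([0.8, 0.3])), np.array([1.0, 0.0]))
    assert loss.item() == pytest.approx(-(math.log(0.8) + math.log(0.7)) / 2)
    assert loss.item() == pytest.approx(0.2899, abs=5e-5)


def test_bce_perfect_prediction_hits_clamp_floor():
    target = np.array([1.0, 0.0, 1.0])
    loss = bce_loss(nn.constant(target.copy()), target)
    assert loss.item() <= 1.1e-7


def test_regularized_loss_values():
    base = nn.constant(1.0)
    params = {"w": nn.parameter(np.array(2.0))}
    assert regularized_loss(base, params, 0.0).item() == 1.0
    assert regularized_loss(base, params, 0.5).item() == pytest.approx(3.0)
    with pytest.raises(ValueError):
        regularized_loss(base, params, -1.0)


def test_regularized_gradient_adds_weight_decay(rng):
    """d(loss + gamma ||W||^2)/dW = dBCE/dW + 2 gamma W (finite differences)."""
    gamma = 1e-2
    w = nn.parameter(rng.normal(size=(5,)))
    target = (rng.uniform(size=(5,)) > 0.5).astype(float)

    def build(track=True):
        pred = nn.sigmoid(w)
        return regularized_loss(bce_loss(pred, target), {"w": w}, gamma)

    loss = build()
    loss.backward()
    analytic = np.array(w.grad)
    h = 1e-6
    for i in range(5):
        orig = w.data[i]
        w.data[i] = orig + h
        lp = build().item()
        w.data[i] = orig - h
        lm = build().item()
        w.data[i] = orig
        numeric = (lp - lm) / (2 * h)
        assert abs(numeric - analytic[i]) < 1e-4 * max(1.0, abs(numeric))
    # and the decay term alone is 2 gamma w on top of the plain BCE gradient
    w.grad = None
    bce_loss(nn.sigmoid(w), target).backward()
    assert np.allclose(analytic - np.array(w.grad), 2 * gamma * w.data, atol=1e-10)


def _toy_pairs(rng, n=4):
    spec = mini_spec()
    pairs = []
    for _ in range(n):
        vol = rng.normal(size=(16, 16, 8))
        holo = rng.normal(size=(16, 16))
        lab = (rng.uniform(size=(16, 16, 8)) > 0.95).astype(np.uint8)
        pairs.append(PatchPair(vol, holo, lab, (0, 0)))
    return spec, pairs


def test_zero_iterations_returns_initial_parameters(rng):
    spec, pairs = _toy_pairs(rng)
    model = ExpertModel(spec, seed=0)
    before = {k: v.data.copy() for k, v in model.params.items()}
    history = train_model(model, pairs, TrainConfig(learning_rate=1e-3,
                                                    max_iterations=0, seed=0))
    assert history.empty
    for k in before:
        assert np.array_equal(model.params[k].data, before[k])


def test_training_is_deterministic_for_fixed_seed(rng):
    spec, pairs = _toy_pairs(rng)
    histories = []
    for _ in range(2):
        model = ExpertModel(spec, seed=3)
        h = train_model(model, pairs, TrainConfig(learning_rate=1e-3,
                                                  max_iterations=12, seed=7,
                                                  validation_interval=4))
        histories.append(h.train_loss.values)
    assert np.array_equal(histories[0], histories[1])


def test_empty_dataset_rejected(rng):
    spec, _ = _toy_pairs(rng)
    with pytest.raises(ValueError, match="empty"):
        train_model(ExpertModel(spec, seed=0), [], TrainConfig(learning_rate=1e-3))


def test_initialize_schemes(rng):
    spec = mini_spec()
    a = initialize(spec, "xavier_all", seed=5)
    b = initialize(spec, "xavier_all", seed=5)
    for k in a.experts[0].params:
        assert np.array_equal(a.experts[0].params[k].data, b.experts[0].params[k].data)
    checkpoints = [ExpertModel(spec, seed=i).params for i in range(3)]
    dsn = initialize(spec, "pretrained_experts", checkpoints, seed=5)
    for i, ckpt in enumerate(checkpoints):
        for k in ckpt:
            assert np.array_equal(dsn.experts[i].params[k].data, ckpt[k].data)
    with pytest.raises(ValueError, match="checkpoints"):
        initialize(spec, "pretrained_experts", None, seed=5)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=1e-3, init_scheme="bogus")


def test_adam_lr_overrides_select_longest_prefix():
    p = {"gtn.fc1.weight": nn.parameter(np.zeros(2)),
         "expert0.head.bias": nn.parameter(np.zeros(2))}
    opt = Adam(p, lr=1e-3, lr_overrides={"gtn.": 1.0})
    for t in p.values():
        t.grad = np.ones(2)
    opt.step()
    assert abs(p["gtn.fc1.weight"].data[0]) > 0.5       # moved at lr ~1
    assert abs(p["expert0.head.bias"].data[0]) < 1e-2   # moved at lr 1e-3


def test_expert_learns_separable_blob_task(rng):
    """Two well-separated bright blobs against background: a mini expert
    reaches > 0.99 per-voxel accuracy (and recovers every blob voxel)."""
    spec = mini_spec()

    def blob_volume(centers):
        ii, jj, kk = np.meshgrid(np.arange(16), np.arange(16), np.arange(8),
                                 indexing="ij")
        x = np.zeros((16, 16, 8))
        lab = np.zeros((16, 16, 8), dtype=np.uint8)
        for ci, cj, ck in centers:
            d2 = (ii - ci) ** 2 + (jj - cj) ** 2 + ((kk - ck) * 2) ** 2
            x += 3.0 * np.exp(-d2 / 6.0)
            lab |= d2 <= 4
        x += 0.1 * rng.normal(size=x.shape)
        return (x - x.mean()) / x.std(), lab

    pairs = []
    for _ in range(6):
        centers = [(rng.integers(3, 7), rng.integers(3, 7), rng.integers(2, 6)),
                   (rng.integers(10, 14), rng.integers(10, 14), rng.integers(2, 6))]
        x, lab = blob_volume(centers)
        pairs.append(PatchPair(x, np.zeros((16, 16)), lab, (0, 0)))

    model = ExpertModel(spec, seed=1)
    history = train_model(model, pairs, TrainConfig(
        learning_rate=1e-2, max_iterations=800, seed=2, validation_interval=200))
    assert history.train_loss.values[-1] < history.train_loss.values[0]
    accuracies, recalls = [], []
    for p in pairs:
        pred = model.forward(p.input_subvolume).data[0].transpose(1, 2, 0) > 0.5
        lab = p.label_subvolume.astype(bool)
        accuracies.append((pred == lab).mean())
        recalls.append(pred[lab].mean())
    assert np.mean(accuracies) > 0.99
    assert np.mean(recalls) > 0.9
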