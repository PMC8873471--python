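import numpy as np
import pytest

from holodsn import nn
from holodsn.dsn_model import (
    ArchitectureSpec,
    DSNModel,
    ExpertModel,
    GatingNetwork,
    SynthesisWeights,
    count_parameters,
    expert_encode,
    expert_param_shapes,
    gtn_param_shapes,
    mini_spec,
    full_scale_spec,
    synthesize_decoder,
    synthesize_features,
    wide_generalist_spec,
)
from holodsn.train import load_checkpoint, save_checkpoint


def test_full_scale_bottleneck_is_8_8_7():
    # 128 -> 64 -> 32 -> 16 -> 8 laterally; 100 -> 50 -> 25 -> 13 -> 7 axially
    assert full_scale_spec().bottleneck_shape() == (8, 8, 7)


def test_scale_shapes_ceil_mode():
    spec = ArchitectureSpec(patch_size=(64, 64), n_slices=20)
    assert spec.scale_shapes() == [(20, 64, 64), (10, 32, 32), (5, 16, 16),
                                   (3, 8, 8), (2, 4, 4)]


def test_mini_forward_matches_shape_arithmetic():
    spec = mini_spec()
    expert = ExpertModel(spec, seed=0)
    pyramid = expert_encode(np.zeros((16, 16, 8)), expert.params, spec)
    d, h, w = spec.scale_shapes()[-1]
    assert pyramid.bottleneck.shape[1:] == (d, h, w)
    out = expert.forward(np.zeros((16, 16, 8)))
    assert out.shape == (1, 8, 16, 16)


def test_encode_rejects_wrong_shape():
    spec = mini_spec()
    expert = ExpertModel(spec, seed=0)
    with pytest.raises(ValueError, match="does not match spec"):
        expert_encode(np.zeros((8, 8, 8)), expert.params, spec)


def test_gtn_alpha_is_normalized(rng):
    gtn = GatingNetwork(mini_spec(), seed=2)
    for _ in range(5):
        alpha = gtn.forward(rng.normal(size=(16, 16))).data
        assert abs(alpha.sum() - 1.0) < 1e-6
        assert np.all(alpha > 0) and np.all(alpha < 1)


def test_gtn_uniform_when_head_is_zero(rng):
    gtn = GatingNetwork(mini_spec(), seed=2)
    gtn.params["fc1.weight"].data[...] = 0.0
    gtn.params["fc1.bias"].data[...] = 0.0
    alpha = gtn.forward(rng.normal(size=(16, 16))).data
    assert np.allclose(alpha, 1.0 / 3.0)


def test_gtn_deterministic(rng):
    gtn = GatingNetwork(mini_spec(), seed=2)
    patch = rng.normal(size=(16, 16))
    a = gtn.forward(patch).data
    b = gtn.forward(patch).data
    assert np.array_equal(a, b)


def test_one_hot_gating_equals_expert_forward(rng):
    """The keystone mechanism: one-hot alpha reduces the synthesized network
    to the corresponding expert, for every expert index."""
    spec = mini_spec()
    dsn = DSNModel(spec, seed=0)
    sub = rng.normal(size=(16, 16, 8))
    for i in range(spec.n_experts):
        alpha = np.zeros(spec.n_experts)
        alpha[i] = 1.0
        mixed = dsn.forward_with_weights(sub, nn.constant(alpha)).data
        pure = dsn.experts[i].forward(sub).data
        assert np.max(np.abs(mixed - pure)) <= 1e-5 * max(np.abs(pure).max(), 1e-30)


def test_feature_synthesis_matches_scalar_loop(rng):
    spec = mini_spec()
    dsn = DSNModel(spec, seed=1)
    sub = rng.normal(size=(16, 16, 8))
    pyramids = [expert_encode(sub, e.params, spec) for e in dsn.experts]
    alpha = np.array([0.2, 0.3, 0.5])
    mixed = synthesize_features(pyramids, nn.constant(alpha))
    # brute-force scalar-loop oracle on the (small) bottleneck
    expected = np.zeros_like(pyramids[0].bottleneck.data)
    for idx in np.ndindex(expected.shape):
        expected[idx] = sum(a * pyramids[i].bottleneck.data[idx]
                            for i, a in enumerate(alpha))
    assert np.allclose(mixed.bottleneck.data, expected, atol=1e-12)
    # and vectorized equality at every skip scale
    for s in range(len(mixed.skips)):
        vec = sum(a * pyramids[i].skips[s].data for i, a in enumerate(alpha))
        assert np.allclose(mixed.skips[s].data, vec, atol=1e-12)


def test_identical_pyramids_are_fixed_point(rng):
    spec = mini_spec()
    expert = ExpertModel(spec, seed=3)
    sub = rng.normal(size=(16, 16, 8))
    pyramid = expert_encode(sub, expert.params, spec)
    pyramids = [expert_encode(sub, expert.params, spec) for _ in range(3)]
    mixed = synthesize_features(pyramids, nn.constant(np.array([0.1, 0.6, 0.3])))
    assert np.allclose(mixed.bottleneck.data, pyramid.bottleneck.data, atol=1e-12)


def test_decoder_synthesis_hand_computation():
    # two-expert toy: every parameter mixes as 0.25 a + 0.75 b
    a = {"dec0.conv0.weight": nn.parameter(np.array([2.0])),
         "head.bias": nn.parameter(np.array([4.0]))}
    b = {"dec0.conv0.weight": nn.parameter(np.array([6.0])),
         "head.bias": nn.parameter(np.array([-4.0]))}
    mixed = synthesize_decoder([a, b], nn.constant(np.array([0.25, 0.75])))
    assert mixed["dec0.conv0.weight"].data == pytest.approx(0.25 * 2 + 0.75 * 6)
    assert mixed["head.bias"].data == pytest.approx(0.25 * 4 + 0.75 * (-4))


def test_decoder_synthesis_key_mismatch_rejected():
    a = {"head.bias": nn.parameter(np.zeros(1))}
    b = {"dec0.conv0.weight": nn.parameter(np.zeros(1))}
    with pytest.raises(ValueError, match="key set"):
        synthesize_decoder([a, b], nn.constant(np.array([0.5, 0.5])))


def test_decoder_mixture_is_linear_in_alpha(rng):
    """D_s depends linearly on alpha: finite differences are constant."""
    spec = mini_spec()
    dsn = DSNModel(spec, seed=4)
    decoders = [e.decoder_params() for e in dsn.experts]
    key = "dec0.conv0.weight"
    base = np.array([0.5, 0.3, 0.2])
    step = np.array([0.1, -0.04, -0.06])
    d0 = synthesize_decoder(decoders, nn.constant(base))[key].data
    d1 = synthesize_decoder(decoders, nn.constant(base + step))[key].data
    d2 = synthesize_decoder(decoders, nn.constant(base + 2 * step))[key].data
    assert np.allclose(d2 - d1, d1 - d0, atol=1e-12)


def test_dsn_output_range_and_determinism(rng):
    spec = mini_spec()
    dsn = DSNModel(spec, seed=5)
    sub = rng.normal(size=(16, 16, 8))
    holo = rng.normal(size=(16, 16))
    out1 = dsn.forward(sub, holo).data
    out2 = dsn.forward(sub, holo).data
    assert np.array_equal(out1, out2)
    assert out1.min() > 0.0 and out1.max() < 1.0


def test_parameter_count_ratio_full_scale():
    expert = count_parameters(expert_param_shapes(full_scale_spec()))
    gtn = count_parameters(gtn_param_shapes(full_scale_spec()))
    ratio = (3 * expert + gtn) / expert
    assert 2.9 <= ratio <= 3.3


def test_wide_generalist_matches_dsn_size():
    expert = count_parameters(expert_param_shapes(full_scale_spec()))
    wide = count_parameters(expert_param_shapes(wide_generalist_spec()))
    assert wide / expert == pytest.approx(3.0, rel=0.1)


def test_channel_doubling_quadruples_conv_parameters():
    def conv_params(base):
        spec = ArchitectureSpec(base_channels=base)
        shapes = expert_param_shapes(spec)
        return int(np.prod(shapes["bott.conv1.weight"]))
    assert conv_params(32) / conv_params(16) == pytest.approx(4.0)


def test_synthesis_weights_validation():
    SynthesisWeights(alpha=np.array([0.2, 0.3, 0.5]))
    with pytest.raises(ValueError):
        SynthesisWeights(alpha=np.array([0.7, 0.7, -0.4]))
    with pytest.raises(ValueError):
        SynthesisWeights(alpha=np.array([0.2, 0.2, 0.2]))


def test_checkpoint_round_trip(tmp_path):
    spec = mini_spec()
    expert = ExpertModel(spec, seed=6)
    path = tmp_path / "expert.npz"
    save_checkpoint(expert.params, path, spec)
    params, loaded_spec = load_checkpoint(path)
    assert loaded_spec == spec
    assert set(params) == set(expert.params)
    for k in params:
        assert np.array_equal(params[k].data, expert.params[k].data)
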