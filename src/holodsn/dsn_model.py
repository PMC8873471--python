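"""Dynamic synthesis network: expert V-nets, gating network, and their mixing.

The descatterer is a mixture-of-experts segmentation network. Each expert is
a 3D V-net (encoder/decoder with skip connections) mapping a standardized
backpropagated sub-volume to a per-voxel particle probability. A small 2D
VGG-style gating network (GTN) looks at the matching hologram patch and emits
synthesis weights alpha (softmax, summing to one). Per input, the network is
synthesized on the fly:

* encoder side — the expert feature pyramids are mixed elementwise,
  F_s = sum_i alpha_i F_i, at every scale including the bottleneck;
* decoder side — the expert decoders' *parameters* are mixed,
  D_s = sum_i alpha_i D_i, and the synthesized decoder is applied to F_s.

Mixed skip features pass straight to the decoder without re-encoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ArchitectureSpec",
    "FeaturePyramid",
    "SynthesisWeights",
    "ExpertModel",
    "GatingNetwork",
    "DSNModel",
    "full_scale_spec",
    "wide_generalist_spec",
    "mini_spec",
    "synthesize_features",
    "synthesize_decoder",
    "count_parameters",
]


def _ceil_div(a: int, b: int) -> int:
    return -(-a // b)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Configurable V-net / GTN geometry.

    ``patch_size`` is the lateral input size (pixels); ``n_slices`` the axial
    input size. Each of the ``n_scales`` encoder stages pools by (2, 2, 2) in
    ceil mode, so the full-scale preset (128 x 128 x 100, 4 stages) bottoms
    out at an 8 x 8 x 7 bottleneck. ``channel_multiplier`` widens every stage
    (sqrt(3) for the parameter-matched wide generalist).
    """

    n_experts: int = 3
    n_scales: int = 4
    base_channels: int = 16
    channel_multiplier: float = 1.0
    patch_size: tuple[int, int] = (128, 128)
    n_slices: int = 100
    kernel: int = 3
    gtn_channels: tuple[int, ...] = (8, 16, 32, 64)
    gtn_hidden: int = 32

    def __post_init__(self):
        if self.n_experts < 2:
            raise ValueError("a mixture needs at least 2 experts")
        if self.n_scales < 1:
            raise ValueError("need at least one encoder scale")

    def stage_channels(self) -> list[int]:
        """Channel width at each encoder stage plus the bottleneck."""
        return [
            max(1, round(self.base_channels * self.channel_multiplier * 2**s))
            for s in range(self.n_scales + 1)
        ]

    def scale_shapes(self) -> list[tuple[int, int, int]]:
        """(axial, lateral, lateral) spatial shape at each scale, finest first.

        Entry s is the shape *entering* stage s; the last entry is the
        bottleneck shape after all poolings.
        """
        d, h, w = self.n_slices, self.patch_size[0], self.patch_size[1]
        shapes = [(d, h, w)]
        for _ in range(self.n_scales):
            d, h, w = _ceil_div(d, 2), _ceil_div(h, 2), _ceil_div(w, 2)
            shapes.append((d, h, w))
        return shapes

    def bottleneck_shape(self) -> tuple[int, int, int]:
        """Bottleneck spatial size as (nx, ny, nz) — (8, 8, 7) at full scale."""
        d, h, w = self.scale_shapes()[-1]
        return (h, w, d)

    def gtn_feature_size(self) -> int:
        """Flattened size of the gating network's final conv feature map."""
        h, w = self.patch_size
        for _ in self.gtn_channels:
            h, w = _ceil_div(h, 2), _ceil_div(w, 2)
        return self.gtn_channels[-1] * h * w


@dataclass
class SynthesisWeights:
    """Gating coefficients alpha: nonnegative, summing to one."""

    alpha: np.ndarray

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if np.any(self.alpha < -1e-9) or abs(self.alpha.sum() - 1.0) > 1e-6:
            raise ValueError(f"invalid synthesis weights {self.alpha}")


@dataclass
class FeaturePyramid:
    """Per-scale encoder features, finest first, plus the bottleneck."""

    skips: list[Tensor]
    bottleneck: Tensor


# -- parameter shape enumeration (shared by init and counting) ---------------

def expert_param_shapes(spec: ArchitectureSpec) -> dict[str, tuple]:
    """Shapes of every learnable expert parameter, keyed by layer name.

    Encoder keys start with ``enc``/``bott``; decoder keys with ``dec``/
    ``head``. The decoder key set is what dynamic decoder synthesis mixes.
    """
    k = spec.kernel
    ch = spec.stage_channels()
    shapes: dict[str, tuple] = {}

    def conv_block(prefix: str, cin: int, cout: int) -> None:
        for j, (ci, co) in enumerate([(cin, cout), (cout, cout)]):
            shapes[f"{prefix}.conv{j}.weight"] = (co, ci, k, k, k)
            shapes[f"{prefix}.conv{j}.bias"] = (co,)
            shapes[f"{prefix}.norm{j}.gamma"] = (co,)
            shapes[f"{prefix}.norm{j}.beta"] = (co,)

    cin = 1
    for s in range(spec.n_scales):
        conv_block(f"enc{s}", cin, ch[s])
        cin = ch[s]
    conv_block("bott", cin, ch[spec.n_scales])
    for s in reversed(range(spec.n_scales)):
        up_channels = ch[s + 1]
        conv_block(f"dec{s}", up_channels + ch[s], ch[s])
    shapes["head.weight"] = (1, ch[0], 1, 1, 1)
    shapes["head.bias"] = (1,)
    return shapes


def gtn_param_shapes(spec: ArchitectureSpec) -> dict[str, tuple]:
    shapes: dict[str, tuple] = {}
    cin = 1
    for j, cout in enumerate(spec.gtn_channels):
        shapes[f"gconv{j}.weight"] = (cout, cin, spec.kernel, spec.kernel)
        shapes[f"gconv{j}.bias"] = (cout,)
        cin = cout
    shapes["fc0.weight"] = (spec.gtn_hidden, spec.gtn_feature_size())
    shapes["fc0.bias"] = (spec.gtn_hidden,)
    shapes["fc1.weight"] = (spec.n_experts, spec.gtn_hidden)
    shapes["fc1.bias"] = (spec.n_experts,)
    return shapes


def _init_params(shapes: dict[str, tuple], rng: np.random.Generator) -> dict[str, Tensor]:
    params: dict[str, Tensor] = {}
    for name, shape in shapes.items():
        if name.endswith(".bias") or name.endswith(".beta"):
            params[name] = nn.parameter(np.zeros(shape))
        elif name.endswith(".gamma"):
            params[name] = nn.parameter(np.ones(shape))
        else:
            params[name] = nn.parameter(nn.xavier_uniform(shape, rng))
    return params


def count_parameters(shapes_or_params) -> int:
    """Total learnable parameter count of a shape dict or parameter dict."""
    total = 0
    for v in shapes_or_params.values():
        total += int(np.prod(v.shape if isinstance(v, Tensor) else v))
    return total


# -- forward passes ----------------------------------------------------------

def _conv_block(x: Tensor, params: dict[str, Tensor], prefix: str) -> Tensor:
    for j in range(2):
        x = nn.conv3d(x, params[f"{prefix}.conv{j}.weight"], params[f"{prefix}.conv{j}.bias"])
        x = nn.instance_norm(x, params[f"{prefix}.norm{j}.gamma"], params[f"{prefix}.norm{j}.beta"])
        x = nn.relu(x)
    return x


def _as_volume_tensor(subvolume) -> Tensor:
    """Accept (px, py, nz) arrays (dataset layout) or ready (1, nz, px, py) tensors."""
    if isinstance(subvolume, Tensor):
        return subvolume
    arr = np.asarray(subvolume, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.transpose(2, 0, 1)[None]  # -> (1, nz, px, py)
    return nn.constant(arr)


def expert_encode(subvolume, params: dict[str, Tensor],
                  spec: ArchitectureSpec) -> FeaturePyramid:
    """Run one expert encoder; returns skips (finest first) plus bottleneck."""
    x = _as_volume_tensor(subvolume)
    expected = (1, spec.n_slices, *spec.patch_size)
    if x.shape != expected:
        raise ValueError(f"input shape {x.shape} does not match spec {expected}")
    skips: list[Tensor] = []
    for s in range(spec.n_scales):
        x = _conv_block(x, params, f"enc{s}")
        skips.append(x)
        x = nn.maxpool3d(x)
    bottleneck = _conv_block(x, params, "bott")
    return FeaturePyramid(skips=skips, bottleneck=bottleneck)


def decode(pyramid: FeaturePyramid, params: dict[str, Tensor],
           spec: ArchitectureSpec) -> Tensor:
    """Run a decoder (expert or synthesized) over a feature pyramid."""
    x = pyramid.bottleneck
    for s in reversed(range(spec.n_scales)):
        skip = pyramid.skips[s]
        x = nn.upsample_nearest3d(x, skip.shape[1:])
        x = nn.concat(x, skip, axis=0)
        x = _conv_block(x, params, f"dec{s}")
    x = nn.conv3d(x, params["head.weight"], params["head.bias"])
    return nn.sigmoid(x)


def synthesize_features(pyramids: list[FeaturePyramid], alpha: Tensor) -> FeaturePyramid:
    """Elementwise mixture F_s = sum_i alpha_i F_i at every scale."""
    n = alpha.shape[0]
    if len(pyramids) != n:
        raise ValueError(f"{len(pyramids)} pyramids for {n} weights")
    n_scales = len(pyramids[0].skips)
    for p in pyramids:
        if len(p.skips) != n_scales or any(
            a.shape != b.shape for a, b in zip(p.skips, pyramids[0].skips)
        ) or p.bottleneck.shape != pyramids[0].bottleneck.shape:
            raise ValueError("expert pyramids are not shape-compatible")

    def mix(tensors: list[Tensor]) -> Tensor:
        acc = nn.mul(nn.index(alpha, 0), tensors[0])
        for i in range(1, n):
            acc = nn.add(acc, nn.mul(nn.index(alpha, i), tensors[i]))
        return acc

    return FeaturePyramid(
        skips=[mix([p.skips[s] for p in pyramids]) for s in range(n_scales)],
        bottleneck=mix([p.bottleneck for p in pyramids]),
    )


def synthesize_decoder(decoders: list[dict[str, Tensor]], alpha: Tensor) -> dict[str, Tensor]:
    """Parameter-level mixture D_s = sum_i alpha_i D_i.

    Every learnable decoder parameter — conv kernels, biases, and the
    normalization affine terms — is mixed with the same weights.
    """
    n = alpha.shape[0]
    if len(decoders) != n:
        raise ValueError(f"{len(decoders)} decoders for {n} weights")
    keys = set(decoders[0])
    for d in decoders[1:]:
        if set(d) != keys:
            raise ValueError("expert decoder key sets differ; cannot mix")
    mixed: dict[str, Tensor] = {}
    for key in decoders[0]:
        acc = nn.mul(nn.index(alpha, 0), decoders[0][key])
        for i in range(1, n):
            acc = nn.add(acc, nn.mul(nn.index(alpha, i), decoders[i][key]))
        mixed[key] = acc
    return mixed


# -- model containers --------------------------------------------------------

class ExpertModel:
    """A single V-net expert (also the baseline/wide generalist)."""

    def __init__(self, spec: ArchitectureSpec, params: dict[str, Tensor] | None = None,
                 seed: int = 0):
        self.spec = spec
        if params is None:
            params = _init_params(expert_param_shapes(spec), np.random.default_rng(seed))
        self.params = params

    def encoder_params(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items()
                if k.startswith("enc") or k.startswith("bott")}

    def decoder_params(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items()
                if k.startswith("dec") or k.startswith("head")}

    def forward(self, subvolume) -> Tensor:
        pyramid = expert_encode(subvolume, self.params, self.spec)
        return decode(pyramid, self.decoder_params(), self.spec)

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def n_parameters(self) -> int:
        return count_parameters(self.params)


class GatingNetwork:
    """VGG-style 2D network predicting the synthesis weights."""

    def __init__(self, spec: ArchitectureSpec, params: dict[str, Tensor] | None = None,
                 seed: int = 0):
        self.spec = spec
        if params is None:
            params = _init_params(gtn_param_shapes(spec), np.random.default_rng(seed))
        self.params = params

    def forward(self, hologram_patch) -> Tensor:
        """Hologram patch (px, py) -> alpha tensor (n_experts,)."""
        if isinstance(hologram_patch, Tensor):
            x = hologram_patch
        else:
            arr = np.asarray(hologram_patch, dtype=np.float64)
            if arr.ndim == 2:
                arr = arr[None]
            x = nn.constant(arr)
        if x.shape[1:] != self.spec.patch_size:
            raise ValueError(
                f"hologram patch {x.shape[1:]} does not match spec {self.spec.patch_size}"
            )
        for j in range(len(self.spec.gtn_channels)):
            x = nn.conv2d(x, self.params[f"gconv{j}.weight"], self.params[f"gconv{j}.bias"])
            x = nn.relu(x)
            x = nn.maxpool2d(x)
        x = nn.flatten(x)
        x = nn.relu(nn.linear(x, self.params["fc0.weight"], self.params["fc0.bias"]))
        logits = nn.linear(x, self.params["fc1.weight"], self.params["fc1.bias"])
        return nn.softmax_vec(logits)

    def predict_weights(self, hologram_patch) -> SynthesisWeights:
        return SynthesisWeights(alpha=self.forward(hologram_patch).data)

    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def n_parameters(self) -> int:
        return count_parameters(self.params)


class DSNModel:
    """Mixture-of-experts descatterer with dynamic synthesis."""

    def __init__(self, spec: ArchitectureSpec,
                 experts: list[ExpertModel] | None = None,
                 gtn: GatingNetwork | None = None,
                 seed: int = 0):
        self.spec = spec
        if experts is None:
            experts = [ExpertModel(spec, seed=seed + i) for i in range(spec.n_experts)]
        if len(experts) != spec.n_experts:
            raise ValueError("expert count does not match spec")
        self.experts = experts
        self.gtn = gtn if gtn is not None else GatingNetwork(spec, seed=seed + 1000)

    def forward_with_weights(self, subvolume, alpha: Tensor) -> Tensor:
        pyramids = [expert_encode(subvolume, e.params, self.spec) for e in self.experts]
        mixed_features = synthesize_features(pyramids, alpha)
        mixed_decoder = synthesize_decoder(
            [e.decoder_params() for e in self.experts], alpha)
        return decode(mixed_features, mixed_decoder, self.spec)

    def forward(self, subvolume, hologram_patch) -> Tensor:
        alpha = self.gtn.forward(hologram_patch)
        return self.forward_with_weights(subvolume, alpha)

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for i, e in enumerate(self.experts):
            for k, v in e.params.items():
                params[f"expert{i}.{k}"] = v
        for k, v in self.gtn.params.items():
            params[f"gtn.{k}"] = v
        return params

    def n_parameters(self) -> int:
        return count_parameters(self.parameters())


# -- presets -----------------------------------------------------------------

def full_scale_spec() -> ArchitectureSpec:
    """Full-scale expert/baseline-generalist geometry (~5.9 M parameters)."""
    return ArchitectureSpec()


def wide_generalist_spec() -> ArchitectureSpec:
    """Single V-net widened by ~sqrt(3) per stage to match the DSN's size."""
    return ArchitectureSpec(channel_multiplier=math.sqrt(3.0))


def mini_spec(patch: int = 16, n_slices: int = 8) -> ArchitectureSpec:
    """Desk-scale geometry for CPU tests and demos."""
    return ArchitectureSpec(
        n_scales=2,
        base_channels=2,
        patch_size=(patch, patch),
        n_slices=n_slices,
        gtn_channels=(4, 8),
        gtn_hidden=8,
    )
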