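"""Loss, optimization, and initialization for the descattering networks.

The training objective is mean per-voxel binary cross-entropy between the
predicted particle-probability volume and the binary ground truth, optionally
with L2 weight decay (loss + gamma * ||W||^2, used for the mixture network).
Optimization is Adam with seeded sample ordering, so a fixed seed reproduces
the loss history exactly.

Two initialization schemes are provided: Xavier everywhere, or experts copied
from pretrained single-condition checkpoints (the gating network is always
Xavier-initialized).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .dsn_model import (
    ArchitectureSpec,
    DSNModel,
    ExpertModel,
    GatingNetwork,
    expert_param_shapes,
    gtn_param_shapes,
    _init_params,
)

__all__ = [
    "TrainConfig",
    "bce_loss",
    "regularized_loss",
    "Adam",
    "initialize",
    "train_model",
    "save_checkpoint",
    "load_checkpoint",
    "FULL_SCALE_TRAIN_CONFIGS",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 1
    max_iterations: int = 1000
    l2_gamma: float = 0.0
    init_scheme: str = "xavier_all"  # or "pretrained_experts"
    seed: int = 0
    validation_interval: int = 100
    #: Optional larger step size for the gating sub-network ("gtn.*" params).
    #: Short desk-scale co-training runs need the gate to move faster than the
    #: experts; full-scale runs leave this None (single learning rate).
    gtn_learning_rate: float | None = None
    #: Restrict optimization to parameters whose name starts with one of these
    #: prefixes (e.g. ("gtn.",) for a gate warm-up phase); None trains all.
    trainable_prefixes: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.l2_gamma < 0:
            raise ValueError("l2_gamma must be nonnegative")
        if self.init_scheme not in ("xavier_all", "pretrained_experts"):
            raise ValueError(f"unknown init scheme {self.init_scheme!r}")


#: Hyperparameters used at full scale for each model kind.
FULL_SCALE_TRAIN_CONFIGS: dict[str, TrainConfig] = {
    "expert": TrainConfig(learning_rate=1e-4, batch_size=4, max_iterations=81_000),
    "generalist": TrainConfig(learning_rate=1e-5, batch_size=20, max_iterations=17_000),
    "wide_generalist": TrainConfig(learning_rate=1e-4, batch_size=1, max_iterations=30_000),
    "dsn": TrainConfig(learning_rate=1e-5, batch_size=1, max_iterations=30_000,
                       l2_gamma=1e-6, init_scheme="pretrained_experts"),
}


def bce_loss(pred, target, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy; see :func:`holodsn.nn.bce`."""
    return nn.bce(pred, target, eps=eps)


def regularized_loss(loss: Tensor, params: dict[str, Tensor], gamma: float) -> Tensor:
    """loss + gamma * sum of squared parameters (gamma = 0 returns loss)."""
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if gamma == 0:
        return loss
    total = loss
    for p in params.values():
        total = nn.add(total, nn.mul(gamma, nn.tsum(nn.mul(p, p))))
    return total


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 lr_overrides: dict[str, float] | None = None):
        self.params = params
        self.lr = lr
        #: prefix -> learning rate; the longest matching prefix wins
        self.lr_overrides = lr_overrides or {}
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            lr = self.lr
            for prefix, value in self.lr_overrides.items():
                if k.startswith(prefix):
                    lr = value
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


def initialize(spec: ArchitectureSpec, scheme: str,
               pretrained_checkpoints: list[dict[str, Tensor]] | None = None,
               seed: int = 0) -> DSNModel:
    """Build a DSN ready for (co-)training.

    ``xavier_all``: experts and GTN all Xavier. ``pretrained_experts``:
    expert parameters copied from the given checkpoints (one per expert, at
    full scale pretrained on densities 3.2, 6.41, 12.82 x10^4 / uL); the GTN
    is Xavier in both schemes.
    """
    rng = np.random.default_rng(seed)
    gtn = GatingNetwork(spec, params=_init_params(gtn_param_shapes(spec), rng))
    if scheme == "xavier_all":
        experts = [
            ExpertModel(spec, params=_init_params(expert_param_shapes(spec), rng))
            for _ in range(spec.n_experts)
        ]
    elif scheme == "pretrained_experts":
        if pretrained_checkpoints is None or len(pretrained_checkpoints) != spec.n_experts:
            raise ValueError(
                f"pretrained_experts needs {spec.n_experts} checkpoints, got "
                f"{0 if pretrained_checkpoints is None else len(pretrained_checkpoints)}"
            )
        experts = []
        for ckpt in pretrained_checkpoints:
            params = {k: nn.parameter(np.array(v.data if isinstance(v, Tensor) else v))
                      for k, v in ckpt.items()}
            if set(params) != set(expert_param_shapes(spec)):
                raise ValueError("checkpoint key set does not match the architecture")
            experts.append(ExpertModel(spec, params=params))
    else:
        raise ValueError(f"unknown init scheme {scheme!r}")
    return DSNModel(spec, experts=experts, gtn=gtn)


def _forward_loss(model, pair, gamma: float) -> Tensor:
    target = np.asarray(pair.label_subvolume, dtype=np.float64)
    if target.ndim == 3:
        target = target.transpose(2, 0, 1)[None]
    if isinstance(model, DSNModel):
        pred = model.forward(pair.input_subvolume, pair.hologram_patch)
    else:
        pred = model.forward(pair.input_subvolume)
    loss = bce_loss(pred, target)
    return regularized_loss(loss, model.parameters(), gamma)


def train_model(model, dataset, config: TrainConfig,
                validation_set=None) -> pd.DataFrame:
    """Stochastic training loop; returns the per-interval loss history.

    ``model`` is an :class:`ExpertModel` (hologram ignored) or a
    :class:`DSNModel`. Samples are drawn uniformly with a seeded generator;
    gradients are averaged over ``batch_size`` samples per step. Divergence
    (NaN loss) aborts with diagnostics.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    trainable = params
    if config.trainable_prefixes is not None:
        trainable = {k: v for k, v in params.items()
                     if any(k.startswith(p) for p in config.trainable_prefixes)}
        if not trainable:
            raise ValueError("no parameters match trainable_prefixes")
    overrides = {}
    if config.gtn_learning_rate is not None:
        overrides["gtn."] = config.gtn_learning_rate
    optimizer = Adam(trainable, lr=config.learning_rate, lr_overrides=overrides)
    records = []
    for it in range(config.max_iterations):
        for p in params.values():
            p.grad = None
        batch_losses = []
        idx = rng.integers(0, len(dataset), size=config.batch_size)
        for i in idx:
            loss = _forward_loss(model, dataset[int(i)], config.l2_gamma)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged at iteration {it}: loss={loss.item()}"
                )
            loss.backward()
            batch_losses.append(loss.item())
        if config.batch_size > 1:
            for p in params.values():
                if p.grad is not None:
                    p.grad /= config.batch_size
        optimizer.step()
        train_loss = float(np.mean(batch_losses))
        if (it + 1) % config.validation_interval == 0 or it == config.max_iterations - 1:
            val_loss = None
            if validation_set:
                val_loss = float(np.mean([
                    _forward_loss(model, pair, 0.0).item() for pair in validation_set
                ]))
            records.append({"iteration": it + 1, "train_loss": train_loss,
                            "val_loss": val_loss})
    return pd.DataFrame.from_records(records)


# -- checkpoints -------------------------------------------------------------

def save_checkpoint(params: dict[str, Tensor], path, spec: ArchitectureSpec | None = None):
    """Write parameters (and optionally the architecture) to an .npz container."""
    arrays = {k: v.data for k, v in params.items()}
    if spec is not None:
        from dataclasses import asdict
        arrays["__spec__"] = np.frombuffer(
            json.dumps(asdict(spec)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Read a checkpoint; returns (params, spec-or-None)."""
    data = np.load(path)
    spec = None
    params: dict[str, Tensor] = {}
    for k in data.files:
        if k == "__spec__":
            payload = json.loads(bytes(data[k].tobytes()).decode())
            for key in ("patch_size", "gtn_channels"):
                payload[key] = tuple(payload[key])
            spec = ArchitectureSpec(**payload)
        else:
            params[k] = nn.parameter(data[k])
    return params, spec
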