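"""Desk-scale end-to-end experiments.

These are scaled-down versions of the full-scale studies: the same physics
(beam-propagation holograms, angular-spectrum backpropagation), the same
network mechanics (pretrained experts, gate warm-up, joint co-training), and
the same scoring, run on a 32 x 32 x 10-voxel coarse grid so a complete
experiment takes a couple of minutes on one CPU. The problem sizes here are
the package's mini study conditions; they are not tuned per run.

The co-training demo uses two scattering conditions that are visually
distinct in the hologram and require different descattering behavior: a
denser field of small (0.8 um) particles versus a sparser field of large
(3 um) particles. Expert specialization across pure density shifts is weak
at this miniature scale (a dense-trained expert transfers well downward), so
the conditions differ in density *and* diameter to give each expert a regime
where it is genuinely the better descatterer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .optics import OpticsConfig, axial_resolution, effective_pixel, lateral_resolution
from .scene import (
    Particle,
    ParticleField,
    make_ground_truth,
    sample_particle_field,
    voxelize,
)
from .bpm import simulate_hologram
from .holo_backprop import backpropagate
from .preprocess import build_dataset
from .dsn_model import ArchitectureSpec, ExpertModel
from .localization_eval import (
    CentroidSet,
    binarize_volume,
    detect_centroids,
    filter_clusters,
    match_and_classify,
)
from .train import TrainConfig, _forward_loss, initialize, train_model

__all__ = [
    "toy_optics",
    "make_condition_pairs",
    "CotrainingResult",
    "mini_dsn_cotraining",
    "groundtruth_selfcheck_ji",
    "backprop_localization_error",
]

logger = logging.getLogger(__name__)


def toy_optics() -> OpticsConfig:
    """16 x 16 x 50 um volume on a 32 x 32 lateral grid (10 coarse slices)."""
    return OpticsConfig(
        magnification=6.9,
        sensor_pixel_um=3.45,
        lateral_extent_x_um=16.0,
        lateral_extent_y_um=16.0,
        axial_extent_um=50.0,
        lateral_pixels_x=32,
        lateral_pixels_y=32,
    )


def make_condition_pairs(count: int, diameter_um: float, seed: int,
                         n_volumes: int = 2, index_contrast: float = 0.2):
    """Simulate ``n_volumes`` scenes of one condition and return patch pairs."""
    optics = toy_optics()
    box = (optics.lateral_extent_x_um, optics.lateral_extent_y_um,
           optics.axial_extent_um)
    volumes, holograms, labels = [], [], []
    for v in range(n_volumes):
        field = sample_particle_field(
            count, box, min_distance_um=diameter_um + 0.3, seed=seed + v,
            diameter_um=diameter_um, index_contrast=index_contrast)
        hologram = simulate_hologram(voxelize(field, optics), optics)
        backprop = backpropagate(hologram, optics)
        volumes.append(np.abs(backprop.values))
        holograms.append(hologram.intensity)
        labels.append(make_ground_truth(field, optics).labels)
    return build_dataset(volumes, holograms, labels,
                         patch=optics.lateral_pixels_x, role="test")


@dataclass
class CotrainingResult:
    """Outcome of the miniature pretrain + co-train experiment."""

    expert_losses: np.ndarray  # (2, 2): [expert, condition] mean BCE
    initial_loss: float  # mixed-set loss of the DSN before co-training
    final_loss: float  # mixed-set loss after warm-up + joint co-training
    alpha_mean_a: np.ndarray
    alpha_mean_b: np.ndarray

    @property
    def separation(self) -> float:
        """Largest component-wise gap between the two conditions' mean alpha."""
        return float(np.abs(self.alpha_mean_a - self.alpha_mean_b).max())


def mini_dsn_cotraining(seed: int = 0) -> CotrainingResult:
    """Pretrain two experts, co-train a 2-expert DSN, measure gate behavior.

    Schedule (desk scale): experts pretrained from a shared initialization on
    their own condition (shared init keeps the two weight vectors linearly
    connected, so blended decoders behave sensibly at intermediate alpha);
    then a gate-only warm-up at a small step size (the gate must discriminate
    before its softmax saturates); then joint co-training of everything, with
    L2 decay, per the mixture network's full-scale recipe.
    """
    logging.disable(logging.WARNING)
    try:
        base = (seed % 2**16) * 131 + 7
        pairs_a = make_condition_pairs(20, 0.8, seed=base)
        pairs_b = make_condition_pairs(5, 3.0, seed=base + 50)
        mixed = pairs_a + pairs_b
        spec = ArchitectureSpec(
            n_experts=2, n_scales=2, base_channels=3, patch_size=(32, 32),
            n_slices=10, gtn_channels=(4, 8), gtn_hidden=8)

        e0 = ExpertModel(spec, seed=base + 1)
        e1 = ExpertModel(spec, seed=base + 1)  # shared initialization
        train_model(e0, pairs_a, TrainConfig(
            learning_rate=1e-2, max_iterations=400, seed=base + 11,
            validation_interval=200))
        train_model(e1, pairs_b, TrainConfig(
            learning_rate=1e-2, max_iterations=400, seed=base + 12,
            validation_interval=200))
        expert_losses = np.array([
            [np.mean([_forward_loss(e, p, 0.0).item() for p in pairs])
             for pairs in (pairs_a, pairs_b)]
            for e in (e0, e1)
        ])

        dsn = initialize(spec, "pretrained_experts", [e0.params, e1.params],
                         seed=base + 3)
        initial_loss = float(np.mean(
            [_forward_loss(dsn, p, 0.0).item() for p in mixed]))
        train_model(dsn, mixed, TrainConfig(
            learning_rate=3e-4, max_iterations=300, seed=base + 100,
            validation_interval=300, trainable_prefixes=("gtn.",)))
        train_model(dsn, mixed, TrainConfig(
            learning_rate=1e-3, gtn_learning_rate=3e-4, max_iterations=150,
            l2_gamma=1e-6, seed=base + 101, validation_interval=150))
        final_loss = float(np.mean(
            [_forward_loss(dsn, p, 0.0).item() for p in mixed]))

        alpha_a = np.array([dsn.gtn.predict_weights(p.hologram_patch).alpha
                            for p in pairs_a])
        alpha_b = np.array([dsn.gtn.predict_weights(p.hologram_patch).alpha
                            for p in pairs_b])
        return CotrainingResult(
            expert_losses=expert_losses,
            initial_loss=initial_loss,
            final_loss=final_loss,
            alpha_mean_a=alpha_a.mean(axis=0),
            alpha_mean_b=alpha_b.mean(axis=0),
        )
    finally:
        logging.disable(logging.NOTSET)


def groundtruth_selfcheck_ji(seed: int = 0) -> float:
    """Score a ground-truth volume against its own particle list.

    Well-separated particles with footprints of at least 10 voxels fed
    directly through binarize -> cluster filter -> centroids -> matching must
    come back with JI = 1.
    """
    optics = toy_optics()
    box = (optics.lateral_extent_x_um, optics.lateral_extent_y_um,
           optics.axial_extent_um)
    # the 12 um disk radius keeps components from merging across the 5 um
    # slice spacing under 26-connectivity
    field = sample_particle_field(3, box, min_distance_um=12.0, seed=seed,
                                  diameter_um=2.0, index_contrast=0.2,
                                  inset_um=2.0)
    truth_volume = make_ground_truth(field, optics)
    prob = truth_volume.labels.astype(float)
    binary = filter_clusters(binarize_volume(prob), min_voxels=10)
    predicted = detect_centroids(binary, optics)
    pts = field.positions()
    pts[:, 2] = optics.axial_extent_um - pts[:, 2]
    truth = CentroidSet(pts, source="ground_truth")
    match = match_and_classify(predicted, truth)
    ji = match.tp / max(match.tp + match.fp + match.fn, 1)
    return float(ji)


def backprop_localization_error(seed: int = 0) -> dict:
    """Locate one weak particle by exhaustive arg-max of |R|.

    Returns the lateral and axial localization error of the brightest voxel
    in the backpropagated volume, in units of the system's lateral and axial
    resolution.
    """
    optics = toy_optics()
    rng = np.random.default_rng(seed)
    x = float(rng.uniform(5.0, 11.0))
    y = float(rng.uniform(5.0, 11.0))
    z = float(rng.uniform(15.0, 35.0))
    field = ParticleField([Particle(x, y, z, 1.0, 1e-2)],
                          box_um=(16.0, 16.0, 50.0))
    hologram = simulate_hologram(voxelize(field, optics), optics)
    volume = backpropagate(hologram, optics)
    amp = np.abs(volume.values)
    i, j, k = np.unravel_index(np.argmax(amp), amp.shape)
    dx = effective_pixel(optics) * 1e-3
    found = np.array([(i + 0.5) * dx, (j + 0.5) * dx,
                      volume.slice_depths_um[k]])
    true = np.array([x, y, optics.axial_extent_um - z])
    lateral_err = float(np.hypot(*(found[:2] - true[:2])))
    axial_err = float(abs(found[2] - true[2]))
    return {
        "lateral_error_um": lateral_err,
        "axial_error_um": axial_err,
        "lateral_error_resolutions": lateral_err / lateral_resolution(optics),
        "axial_error_resolutions": axial_err / axial_resolution(optics),
    }
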