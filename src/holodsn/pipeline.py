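"""Reproducible simulate -> backpropagate -> dataset -> train -> evaluate runs.

Each stage reads the previous stage's artifacts from a run directory, writes
its own, and records them (with SHA-256 checksums, the config hash, and the
seeds used) in ``manifest.json``. Deterministic stages re-run with the same
config and seed reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import __version__
from .optics import OpticsConfig, mini_config, full_scale_config
from .scene import (
    ParticleField,
    density_to_count,
    make_ground_truth,
    sample_heterogeneity,
    sample_particle_field,
    voxelize,
)
from .bpm import Hologram, simulate_hologram
from .holo_backprop import backpropagate
from .preprocess import build_dataset, normalize, patch_origins
from .dsn_model import DSNModel, ExpertModel, mini_spec
from .localization_eval import (
    CentroidSet,
    binarize_volume,
    depthwise_ji,
    detect_centroids,
    filter_clusters,
    match_and_classify,
)
from .train import TrainConfig, load_checkpoint, save_checkpoint, train_model

__all__ = [
    "ExperimentManifest",
    "MissingArtifactError",
    "run_stage",
    "make_condition_grid",
    "STAGES",
]

SEEN_DENSITIES_E4 = [1.6, 3.2, 6.41, 12.82]
UNSEEN_DENSITIES_E4 = [2.24, 4.81, 9.61, 19.23, 25.64]


class MissingArtifactError(FileNotFoundError):
    """An upstream stage has not produced its artifacts yet."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class ExperimentManifest:
    """Record of every stage's artifacts, config hash, and seed."""

    root: Path
    stages: dict = field(default_factory=dict)
    version: str = __version__

    @property
    def path(self) -> Path:
        return Path(self.root) / "manifest.json"

    def record(self, stage: str, config: dict, seed: int, artifacts: list[Path]) -> None:
        self.stages[stage] = {
            "config_hash": _config_hash(config),
            "seed": seed,
            "artifacts": {
                str(Path(p).relative_to(self.root)): _sha256(Path(p)) for p in artifacts
            },
        }
        self.save()

    def save(self) -> None:
        payload = {"version": self.version, "stages": self.stages}
        with open(self.path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def load(cls, root) -> "ExperimentManifest":
        root = Path(root)
        manifest = cls(root=root)
        if manifest.path.exists():
            with open(manifest.path) as fh:
                payload = json.load(fh)
            manifest.stages = payload.get("stages", {})
            manifest.version = payload.get("version", __version__)
        return manifest

    def validate(self) -> bool:
        """Re-checksum every recorded artifact; raises on mismatch."""
        for stage, entry in self.stages.items():
            for rel, digest in entry["artifacts"].items():
                p = Path(self.root) / rel
                if not p.exists():
                    raise MissingArtifactError(f"{stage}: missing artifact {rel}")
                if _sha256(p) != digest:
                    raise ValueError(f"{stage}: checksum mismatch for {rel}")
        return True


def make_condition_grid(spec: dict | str) -> list[dict]:
    """Expand a condition-group name (or explicit spec) into condition records.

    Groups mirror the seen-density training grid and the unseen-condition
    test grids: densities, diameters, index contrasts, combined shifts, and
    uniform heterogeneity in contrast and/or diameter.
    """
    base = {"diameter_um": 1.0, "dn": 0.26, "delta_n_pct": 0.0,
            "delta_d_pct": 0.0, "n_volumes": 10}
    if isinstance(spec, dict):
        if not spec:
            return []
        groups = spec.get("groups", [])
        out = []
        for g in groups:
            out.extend(make_condition_grid(g))
        for override in spec.get("conditions", []):
            out.append({**base, **override})
        return out
    name = spec
    if name == "seen_densities":
        return [{**base, "group": name, "density_e4": d} for d in SEEN_DENSITIES_E4]
    if name == "unseen_densities":
        return [{**base, "group": name, "density_e4": d} for d in UNSEEN_DENSITIES_E4]
    if name == "unseen_diameters":
        return [{**base, "group": name, "density_e4": 6.41, "diameter_um": d}
                for d in [0.30, 0.60, 1.40, 1.80]]
    if name == "unseen_dn":
        return [{**base, "group": name, "density_e4": 6.41, "dn": dn}
                for dn in [0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50]]
    if name == "unseen_diameter_dn":
        return [{**base, "group": name, "density_e4": 6.41, "diameter_um": d, "dn": dn}
                for d in [0.30, 0.60, 1.30, 1.50] for dn in [0.10, 0.50]]
    if name == "unseen_all":
        return [{**base, "group": name, "density_e4": d, "diameter_um": 0.60, "dn": 0.10}
                for d in UNSEEN_DENSITIES_E4]
    if name == "random_dn":
        return [{**base, "group": name, "density_e4": 6.41, "dn": 0.20,
                 "delta_n_pct": p} for p in [5.0, 12.5, 25.0, 50.0]]
    if name == "random_diameter":
        return [{**base, "group": name, "density_e4": 6.41, "dn": 0.20,
                 "delta_d_pct": p} for p in [9.0, 17.5, 26.0, 34.5]]
    if name == "random_both":
        return [{**base, "group": name, "density_e4": 6.41, "dn": 0.20,
                 "delta_n_pct": pn, "delta_d_pct": pd}
                for pn, pd in [(5.0, 9.0), (12.5, 17.5), (25.0, 26.0), (50.0, 34.5)]]
    raise ValueError(f"unknown condition group {name!r}")


# -- stages ------------------------------------------------------------------

def _optics_for(preset: str) -> OpticsConfig:
    if preset == "full":
        return full_scale_config()
    if preset == "mini":
        return mini_config()
    raise ValueError(f"unknown preset {preset!r}")


def _field_depths_um(field_particles: ParticleField, config: OpticsConfig) -> np.ndarray:
    """Ground-truth centroid coordinates in backprop depth convention."""
    pts = field_particles.positions().copy()
    pts[:, 2] = config.axial_extent_um - pts[:, 2]
    return pts


def stage_simulate(config: dict, root: Path, seed: int) -> list[Path]:
    """Sample particle fields and simulate their holograms."""
    optics = _optics_for(config.get("preset", "mini"))
    n_volumes = int(config.get("n_volumes", 1))
    count = config.get("count")
    if count is None:
        box = (optics.lateral_extent_x_um, optics.lateral_extent_y_um,
               optics.axial_extent_um)
        count = density_to_count(config["density_e4"] * 1e4, box)
    diameter = float(config.get("diameter_um", 1.0))
    dn = float(config.get("dn", 0.26))
    out = Path(root) / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    artifacts = []
    box = (optics.lateral_extent_x_um, optics.lateral_extent_y_um, optics.axial_extent_um)
    for v in range(n_volumes):
        vol_seed = seed + 101 * v
        field = sample_particle_field(
            count, box, min_distance_um=config.get("min_distance_um", diameter),
            seed=vol_seed, diameter_um=diameter, index_contrast=dn)
        if config.get("delta_n_pct", 0) or config.get("delta_d_pct", 0):
            field = sample_heterogeneity(
                field, dn, config.get("delta_n_pct", 0.0), diameter,
                config.get("delta_d_pct", 0.0), seed=vol_seed + 17)
        index_volume = voxelize(field, optics)
        hologram = simulate_hologram(index_volume, optics,
                                     noise_std=config.get("noise_std", 0.0),
                                     noise_seed=vol_seed + 29)
        truth = make_ground_truth(field, optics)
        particles_csv = out / f"particles_{v:03d}.csv"
        holo_tiff = out / f"hologram_{v:03d}.tiff"
        truth_h5 = out / f"truth_{v:03d}.h5"
        field.to_csv(particles_csv)
        hologram.to_tiff(holo_tiff)
        with h5py.File(truth_h5, "w") as fh:
            fh.create_dataset("labels", data=truth.labels, compression="gzip")
        artifacts += [particles_csv, holo_tiff, truth_h5]
    return artifacts


def stage_backprop(config: dict, root: Path, seed: int) -> list[Path]:
    optics = _optics_for(config.get("preset", "mini"))
    sim = Path(root) / "simulate"
    holos = sorted(sim.glob("hologram_*.tiff"))
    if not holos:
        raise MissingArtifactError("no holograms found; run the simulate stage first")
    out = Path(root) / "backprop"
    out.mkdir(parents=True, exist_ok=True)
    artifacts = []
    for holo_path in holos:
        holo = Hologram.from_tiff(holo_path, provenance="simulated")
        volume = backpropagate(holo, optics)
        dest = out / (holo_path.stem.replace("hologram", "backprop") + ".h5")
        with h5py.File(dest, "w") as fh:
            fh.create_dataset("amplitude", data=volume.amplitude(), compression="gzip")
            fh.attrs["slice_depths_um"] = volume.slice_depths_um
        artifacts.append(dest)
    return artifacts


def stage_dataset(config: dict, root: Path, seed: int) -> list[Path]:
    sim = Path(root) / "simulate"
    bp = Path(root) / "backprop"
    holos = sorted(sim.glob("hologram_*.tiff"))
    backprops = sorted(bp.glob("backprop_*.h5"))
    truths = sorted(sim.glob("truth_*.h5"))
    if not (holos and backprops and truths):
        raise MissingArtifactError(
            "dataset stage needs simulate and backprop artifacts; run those first")
    volumes, holograms, labels = [], [], []
    for h, b, t in zip(holos, backprops, truths):
        holograms.append(Hologram.from_tiff(h).intensity)
        with h5py.File(b, "r") as fh:
            volumes.append(fh["amplitude"][...])
        with h5py.File(t, "r") as fh:
            labels.append(fh["labels"][...])
    patch = int(config.get("patch", volumes[0].shape[0]))
    role = config.get("role", "train")
    pairs = build_dataset(volumes, holograms, labels, patch=patch, role=role)
    out = Path(root) / "dataset"
    out.mkdir(parents=True, exist_ok=True)
    dest = out / f"{role}.h5"
    with h5py.File(dest, "w") as fh:
        fh.create_dataset("inputs", data=np.stack([p.input_subvolume for p in pairs]),
                          compression="gzip")
        fh.create_dataset("holograms", data=np.stack([p.hologram_patch for p in pairs]),
                          compression="gzip")
        fh.create_dataset("labels", data=np.stack([p.label_subvolume for p in pairs]),
                          compression="gzip")
        fh.create_dataset("origins", data=np.array([p.origin for p in pairs]))
    info = out / f"{role}_manifest.json"
    with open(info, "w") as fh:
        json.dump({"n_pairs": len(pairs), "patch": patch, "role": role,
                   "config_hash": _config_hash(config)}, fh, indent=2)
    return [dest, info]


def _load_pairs(path: Path):
    from .preprocess import PatchPair
    with h5py.File(path, "r") as fh:
        inputs = fh["inputs"][...]
        holograms = fh["holograms"][...]
        labels = fh["labels"][...]
        origins = fh["origins"][...]
    return [PatchPair(inputs[i], holograms[i], labels[i], tuple(origins[i]))
            for i in range(len(inputs))]


def stage_train(config: dict, root: Path, seed: int) -> list[Path]:
    dataset_path = Path(root) / "dataset" / "train.h5"
    if not dataset_path.exists():
        raise MissingArtifactError("no training dataset; run the dataset stage first")
    pairs = _load_pairs(dataset_path)
    patch = pairs[0].input_subvolume.shape[0]
    n_slices = pairs[0].input_subvolume.shape[2]
    spec = mini_spec(patch=patch, n_slices=n_slices)
    kind = config.get("model", "dsn")
    tc = TrainConfig(
        learning_rate=float(config.get("learning_rate", 1e-3)),
        batch_size=int(config.get("batch_size", 1)),
        max_iterations=int(config.get("max_iterations", 50)),
        l2_gamma=float(config.get("l2_gamma", 1e-6 if kind == "dsn" else 0.0)),
        seed=seed,
        validation_interval=int(config.get("validation_interval", 10)),
    )
    model = DSNModel(spec, seed=seed) if kind == "dsn" else ExpertModel(spec, seed=seed)
    history = train_model(model, pairs, tc)
    out = Path(root) / "train"
    out.mkdir(parents=True, exist_ok=True)
    ckpt = out / f"{kind}_checkpoint.npz"
    hist = out / f"{kind}_history.csv"
    save_checkpoint(model.parameters(), ckpt, spec)
    history.to_csv(hist, index=False)
    return [ckpt, hist]


def stage_infer(config: dict, root: Path, seed: int) -> list[Path]:
    kind = config.get("model", "dsn")
    ckpt = Path(root) / "train" / f"{kind}_checkpoint.npz"
    if not ckpt.exists():
        raise MissingArtifactError(
            f"no trained {kind} model; run the train stage first")
    params, spec = load_checkpoint(ckpt)
    if kind == "dsn":
        model = DSNModel(spec, seed=seed)
        for name, tensor in model.parameters().items():
            tensor.data[...] = params[name].data
    else:
        model = ExpertModel(spec, params=params)
    bp = Path(root) / "backprop"
    sim = Path(root) / "simulate"
    backprops = sorted(bp.glob("backprop_*.h5"))
    holos = sorted(sim.glob("hologram_*.tiff"))
    if not backprops:
        raise MissingArtifactError("no backpropagated volumes; run backprop first")
    out = Path(root) / "infer"
    out.mkdir(parents=True, exist_ok=True)
    artifacts = []
    patch = spec.patch_size[0]
    for b, h in zip(backprops, holos):
        with h5py.File(b, "r") as fh:
            amplitude = fh["amplitude"][...]
        intensity = Hologram.from_tiff(h).intensity
        namp = normalize(amplitude).values
        nholo = normalize(intensity).values
        prob = np.zeros_like(namp)
        for x0 in patch_origins(namp.shape[0], patch, patch):
            for y0 in patch_origins(namp.shape[1], patch, patch):
                sub = namp[x0:x0 + patch, y0:y0 + patch, :]
                hp = nholo[x0:x0 + patch, y0:y0 + patch]
                if isinstance(model, DSNModel):
                    pred = model.forward(sub, hp)
                else:
                    pred = model.forward(sub)
                prob[x0:x0 + patch, y0:y0 + patch, :] = pred.data[0].transpose(1, 2, 0)
        dest = out / (b.stem.replace("backprop", "probability") + ".h5")
        with h5py.File(dest, "w") as fh:
            fh.create_dataset("probability", data=prob, compression="gzip")
        artifacts.append(dest)
    return artifacts


def stage_evaluate(config: dict, root: Path, seed: int) -> list[Path]:
    optics = _optics_for(config.get("preset", "mini"))
    sim = Path(root) / "simulate"
    inf = Path(root) / "infer"
    probs = sorted(inf.glob("probability_*.h5"))
    particles = sorted(sim.glob("particles_*.csv"))
    if not probs:
        raise MissingArtifactError("no probability volumes; run infer first")
    box = (optics.lateral_extent_x_um, optics.lateral_extent_y_um, optics.axial_extent_um)
    matches = []
    for p_path, csv_path in zip(probs, particles):
        with h5py.File(p_path, "r") as fh:
            prob = fh["probability"][...]
        binary = filter_clusters(binarize_volume(prob),
                                 min_voxels=int(config.get("min_voxels", 10)))
        predicted = detect_centroids(binary, optics)
        field = ParticleField.from_csv(csv_path, box)
        truth = CentroidSet(_field_depths_um(field, optics), source="ground_truth")
        matches.append(match_and_classify(predicted, truth))
    report = depthwise_ji(matches, optics,
                          bin_slices=int(config.get("bin_slices", 10)))
    out = Path(root) / "evaluate"
    out.mkdir(parents=True, exist_ok=True)
    dest = out / "localization_report.json"
    report.to_json(dest)
    return [dest]


def stage_weights_stats(config: dict, root: Path, seed: int) -> list[Path]:
    from .localization_eval import weight_statistics
    kind = "dsn"
    ckpt = Path(root) / "train" / f"{kind}_checkpoint.npz"
    if not ckpt.exists():
        raise MissingArtifactError("weights-stats needs a trained DSN; run train first")
    params, spec = load_checkpoint(ckpt)
    model = DSNModel(spec, seed=seed)
    for name, tensor in model.parameters().items():
        tensor.data[...] = params[name].data
    sim = Path(root) / "simulate"
    holos = sorted(sim.glob("hologram_*.tiff"))
    if not holos:
        raise MissingArtifactError("no holograms; run simulate first")
    patch = spec.patch_size[0]
    alphas = []
    for h in holos:
        nholo = normalize(Hologram.from_tiff(h).intensity).values
        for x0 in patch_origins(nholo.shape[0], patch, patch):
            for y0 in patch_origins(nholo.shape[1], patch, patch):
                alpha = model.gtn.predict_weights(nholo[x0:x0 + patch, y0:y0 + patch])
                alphas.append(alpha.alpha)
    stats = weight_statistics({"all": np.array(alphas)})
    out = Path(root) / "weights_stats"
    out.mkdir(parents=True, exist_ok=True)
    dest = out / "weights_stats.csv"
    stats.to_csv(dest, index=False)
    return [dest]


STAGES = {
    "simulate": stage_simulate,
    "backprop": stage_backprop,
    "dataset": stage_dataset,
    "train": stage_train,
    "infer": stage_infer,
    "evaluate": stage_evaluate,
    "weights-stats": stage_weights_stats,
}


def run_stage(stage: str, config: dict, root, seed: int = 0) -> ExperimentManifest:
    """Run one pipeline stage and record its artifacts in the manifest."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(STAGES)}")
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    artifacts = STAGES[stage](config, root, seed)
    manifest = ExperimentManifest.load(root)
    manifest.record(stage, config, seed, artifacts)
    return manifest
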