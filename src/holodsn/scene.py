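"""Synthetic 3D particle scenes.

Scenes are collections of spherical scatterers (polystyrene-bead-like) in a
rectangular water volume. Particle centers are placed by Poisson-disk (dart
throwing) sampling so no two particles overlap; per-particle diameter and
refractive-index contrast can be heterogeneous (uniform distributions around
central values). Scenes are rasterized twice: onto the fine axial grid as a
refractive-index-contrast volume (the forward model's input) and onto the
coarse axial grid as a binary ground-truth label volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .optics import OpticsConfig, effective_pixel, grid_dimensions

__all__ = [
    "Particle",
    "ParticleField",
    "IndexVolume",
    "GroundTruthVolume",
    "PackingError",
    "density_to_count",
    "sample_particle_field",
    "sample_heterogeneity",
    "voxelize",
    "make_ground_truth",
]

logger = logging.getLogger(__name__)

UM3_PER_UL = 1e9  # 1 uL = 1 mm^3 = 1e9 um^3


class PackingError(RuntimeError):
    """Dart throwing could not place the requested number of particles."""


@dataclass(frozen=True)
class Particle:
    x_um: float
    y_um: float
    z_um: float
    diameter_um: float
    index_contrast: float


@dataclass
class ParticleField:
    """A latent 3D scene: spheres inside a box.

    ``box_um`` is (Lx, Ly, Lz); ``min_distance_um`` records the Poisson-disk
    radius the centers were sampled with (testable after the fact).
    """

    particles: list[Particle]
    box_um: tuple[float, float, float]
    seed: int | None = None
    min_distance_um: float | None = None

    def __len__(self) -> int:
        return len(self.particles)

    def positions(self) -> np.ndarray:
        return np.array([[p.x_um, p.y_um, p.z_um] for p in self.particles]).reshape(-1, 3)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_um": [p.x_um for p in self.particles],
                "y_um": [p.y_um for p in self.particles],
                "z_um": [p.z_um for p in self.particles],
                "diameter_um": [p.diameter_um for p in self.particles],
                "dn": [p.index_contrast for p in self.particles],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, box_um) -> "ParticleField":
        df = pd.read_csv(path)
        particles = [
            Particle(r.x_um, r.y_um, r.z_um, r.diameter_um, r.dn)
            for r in df.itertuples(index=False)
        ]
        return cls(particles=particles, box_um=tuple(box_um))


@dataclass
class IndexVolume:
    """Refractive-index contrast per fine-grid voxel; background is exactly 0."""

    values: np.ndarray  # (nx, ny, n_fine_z) float
    config: OpticsConfig = dataclass_field(repr=False, default=None)


@dataclass
class GroundTruthVolume:
    """Binary particle/background labels on the coarse axial grid."""

    labels: np.ndarray  # (nx, ny, n_coarse_z) uint8
    config: OpticsConfig = dataclass_field(repr=False, default=None)


def density_to_count(density_per_ul: float, box_um: tuple[float, float, float]) -> int:
    """Particle count for a number density (particles/uL) in a box (um^3).

    1.6e4 / uL in the 176.64 x 176.64 x 500 um^3 volume gives 250 particles.
    """
    if density_per_ul < 0:
        raise ValueError("density must be nonnegative")
    volume_um3 = box_um[0] * box_um[1] * box_um[2]
    if volume_um3 <= 0:
        raise ValueError("box volume must be positive")
    return int(round(density_per_ul * volume_um3 / UM3_PER_UL))


def sample_particle_field(
    count: int,
    box_um: tuple[float, float, float],
    min_distance_um: float,
    seed: int,
    diameter_um: float = 1.0,
    index_contrast: float = 0.26,
    max_attempts_per_particle: int = 2000,
    inset_um: float = 0.0,
) -> ParticleField:
    """Place ``count`` sphere centers by Poisson-disk dart throwing.

    Candidate centers are drawn uniformly over the box (optionally inset by
    ``inset_um`` from every face, e.g. by the particle radius to avoid
    clipped spheres) and rejected if closer than ``min_distance_um`` to any
    accepted center. Deterministic for a fixed seed. Raises
    :class:`PackingError` when the attempt budget runs out (infeasible
    packing), reporting how many centers were placed.
    """
    if count < 0:
        raise ValueError("count must be nonnegative")
    rng = np.random.default_rng(seed)
    box = np.asarray(box_um, dtype=float)
    if inset_um < 0 or np.any(2 * inset_um >= box):
        raise ValueError("inset must be nonnegative and smaller than half the box")
    accepted: list[np.ndarray] = []
    budget = max_attempts_per_particle * max(count, 1)
    attempts = 0
    while len(accepted) < count:
        if attempts >= budget:
            raise PackingError(
                f"placed {len(accepted)}/{count} particles after {attempts} "
                f"attempts (min_distance={min_distance_um} um, box={box_um})"
            )
        candidate = inset_um + rng.uniform(0.0, 1.0, size=3) * (box - 2 * inset_um)
        attempts += 1
        if accepted:
            d2 = np.sum((np.array(accepted) - candidate) ** 2, axis=1)
            if d2.min() < min_distance_um**2:
                continue
        accepted.append(candidate)
    particles = [
        Particle(float(c[0]), float(c[1]), float(c[2]), diameter_um, index_contrast)
        for c in accepted
    ]
    return ParticleField(
        particles=particles,
        box_um=tuple(float(b) for b in box),
        seed=seed,
        min_distance_um=min_distance_um,
    )


def sample_heterogeneity(
    field: ParticleField,
    central_dn: float,
    delta_n_pct: float,
    central_diameter_um: float,
    delta_d_pct: float,
    seed: int,
) -> ParticleField:
    """Draw per-particle contrast and diameter from uniform distributions.

    Contrast ~ U(dn*(1 - delta_n), dn*(1 + delta_n)) with delta_n given in
    percent of the central value; diameters analogously. delta = 0 reproduces
    the central values exactly.
    """
    if central_dn < 0 or central_diameter_um <= 0:
        raise ValueError("central values must be positive")
    for delta in (delta_n_pct, delta_d_pct):
        if not 0 <= delta <= 100:
            raise ValueError("heterogeneity percentages must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    n = len(field)
    dn = central_dn * (1.0 + (delta_n_pct / 100.0) * rng.uniform(-1, 1, size=n))
    dia = central_diameter_um * (1.0 + (delta_d_pct / 100.0) * rng.uniform(-1, 1, size=n))
    particles = [
        Particle(p.x_um, p.y_um, p.z_um, float(d), float(c))
        for p, d, c in zip(field.particles, dia, dn)
    ]
    return ParticleField(
        particles=particles,
        box_um=field.box_um,
        seed=seed,
        min_distance_um=field.min_distance_um,
    )


def _grid_coords(config: OpticsConfig):
    nx, ny, n_fine, n_coarse = grid_dimensions(config)
    dx = effective_pixel(config) * 1e-3  # um
    dz_fine = config.fine_axial_step_nm * 1e-3
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dx
    zs = (np.arange(n_fine) + 0.5) * dz_fine
    return xs, ys, zs


def voxelize(field: ParticleField, config: OpticsConfig) -> IndexVolume:
    """Rasterize spheres onto the fine grid.

    A voxel takes a particle's index contrast iff its center lies inside that
    sphere (no antialiasing). Particles protruding past the grid are clipped
    with a logged warning.
    """
    nx, ny, n_fine, _ = grid_dimensions(config)
    xs, ys, zs = _grid_coords(config)
    dx = effective_pixel(config) * 1e-3
    dz = config.fine_axial_step_nm * 1e-3
    values = np.zeros((nx, ny, n_fine), dtype=np.float32)
    extent = (config.lateral_extent_x_um, config.lateral_extent_y_um, config.axial_extent_um)
    for p in field.particles:
        r = p.diameter_um / 2.0
        if (
            p.x_um - r < 0 or p.x_um + r > extent[0]
            or p.y_um - r < 0 or p.y_um + r > extent[1]
            or p.z_um - r < 0 or p.z_um + r > extent[2]
        ):
            logger.warning("particle at (%.2f, %.2f, %.2f) um clipped at grid edge",
                           p.x_um, p.y_um, p.z_um)
        # bounding box of candidate voxels
        ix = np.searchsorted(xs, [p.x_um - r - dx, p.x_um + r + dx])
        iy = np.searchsorted(ys, [p.y_um - r - dx, p.y_um + r + dx])
        iz = np.searchsorted(zs, [p.z_um - r - dz, p.z_um + r + dz])
        sx, sy, sz = slice(*ix), slice(*iy), slice(*iz)
        if xs[sx].size == 0 or ys[sy].size == 0 or zs[sz].size == 0:
            continue
        d2 = (
            (xs[sx, None, None] - p.x_um) ** 2
            + (ys[None, sy, None] - p.y_um) ** 2
            + (zs[None, None, sz] - p.z_um) ** 2
        )
        inside = d2 <= r * r
        values[sx, sy, sz][inside] = p.index_contrast
    return IndexVolume(values=values, config=config)


def fine_to_coarse_slice_map(config: OpticsConfig) -> np.ndarray:
    """Nearest coarse-slice index for every fine slice.

    The coarse grid is co-registered with the backpropagated volume, which is
    indexed by depth *behind the hologram plane* (the exit face of the
    volume): coarse slice j (0-based) is centered at depth (j + 1) * backprop
    step, tiling (0, axial_extent] shallow to deep. A fine slice at scene
    coordinate z sits at depth L - z and maps to the nearest coarse center.
    """
    _, _, n_fine, n_coarse = grid_dimensions(config)
    dz_fine = config.fine_axial_step_nm * 1e-3
    dz_coarse = config.backprop_axial_step_um
    depth_fine = config.axial_extent_um - (np.arange(n_fine) + 0.5) * dz_fine
    depth_coarse = (np.arange(n_coarse) + 1.0) * dz_coarse
    idx = np.abs(depth_fine[:, None] - depth_coarse[None, :]).argmin(axis=1)
    return idx


def make_ground_truth(field: ParticleField, config: OpticsConfig) -> GroundTruthVolume:
    """Binary labels on the coarse grid by nearest-slice axial projection.

    A coarse voxel is 1 iff any fine voxel mapping to it lies inside a
    particle (logical OR within each axial bin).
    """
    nx, ny, n_fine, n_coarse = grid_dimensions(config)
    index_volume = voxelize(field, config)
    occupancy = index_volume.values != 0
    slice_map = fine_to_coarse_slice_map(config)
    labels = np.zeros((nx, ny, n_coarse), dtype=np.uint8)
    for j in range(n_coarse):
        sel = slice_map == j
        if sel.any():
            labels[:, :, j] = occupancy[:, :, sel].any(axis=2)
    return GroundTruthVolume(labels=labels, config=config)
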