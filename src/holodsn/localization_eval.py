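"""3D particle-localization scoring.

The network output (a per-voxel particle probability volume) is turned into
a particle list and compared against ground truth:

1. slice-wise Otsu binarization;
2. removal of connected components smaller than 10 voxels (26-connectivity);
3. per-component centroids, converted to micrometres;
4. minimum-total-distance one-to-one assignment between predicted and true
   centroids, then TP/FP/FN labelling with an elliptical proximity gate of
   4 x 4 x 12 um (semi-axes 2, 2, 6 um);
5. Jaccard index JI = TP / (TP + FP + FN), reported per 10-slice depth bin
   (every 50 um at the full-scale 5 um slice spacing) with mean/std across
   volumes.

Synthesis-weight statistics (mean/std of alpha per scattering condition) are
also computed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu

from .optics import OpticsConfig, effective_pixel

__all__ = [
    "CentroidSet",
    "MatchResult",
    "LocalizationReport",
    "binarize_volume",
    "filter_clusters",
    "detect_centroids",
    "match_and_classify",
    "jaccard_index",
    "depthwise_ji",
    "weight_statistics",
]

DEFAULT_GATE_UM = (4.0, 4.0, 12.0)  # full ellipse dimensions, not semi-axes


@dataclass
class CentroidSet:
    """Particle centroids in um; z is depth behind the hologram plane."""

    points_um: np.ndarray  # (n, 3)
    source: str = "predicted"  # or "ground_truth"

    def __post_init__(self):
        self.points_um = np.asarray(self.points_um, dtype=np.float64).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points_um)


@dataclass
class MatchResult:
    """TP/FP/FN labelling of one predicted-vs-truth comparison."""

    tp_pairs: list[tuple[int, int]]  # (predicted index, truth index)
    fp_indices: list[int]  # predicted
    fn_indices: list[int]  # truth
    predicted: CentroidSet
    truth: CentroidSet

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def fp(self) -> int:
        return len(self.fp_indices)

    @property
    def fn(self) -> int:
        return len(self.fn_indices)


@dataclass
class LocalizationReport:
    """Per-volume match results plus depth-binned Jaccard curves."""

    matches: list[MatchResult]
    bin_edges_um: np.ndarray | None = None
    per_volume_bin_ji: np.ndarray | None = None  # (n_volumes, n_bins), NaN = empty bin
    bin_mean: np.ndarray | None = None
    bin_std: np.ndarray | None = None

    @property
    def tp(self) -> int:
        return sum(m.tp for m in self.matches)

    @property
    def fp(self) -> int:
        return sum(m.fp for m in self.matches)

    @property
    def fn(self) -> int:
        return sum(m.fn for m in self.matches)

    def global_ji(self) -> float | None:
        return jaccard_index(self.tp, self.fp, self.fn)

    def to_json(self, path) -> None:
        payload = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "global_ji": self.global_ji(),
            "bin_edges_um": None if self.bin_edges_um is None else list(self.bin_edges_um),
            "bin_mean": None if self.bin_mean is None else [
                None if np.isnan(v) else float(v) for v in self.bin_mean],
            "bin_std": None if self.bin_std is None else [
                None if np.isnan(v) else float(v) for v in self.bin_std],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def binarize_volume(prob_volume: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Threshold each axial slice independently with Otsu's method.

    ``prob_volume`` is (nx, ny, nz) with values in [0, 1]. Slices with
    negligible dynamic range (< 1e-6) are set to all-background.
    """
    prob_volume = np.asarray(prob_volume, dtype=np.float64)
    binary = np.zeros(prob_volume.shape, dtype=np.uint8)
    for j in range(prob_volume.shape[2]):
        sl = prob_volume[:, :, j]
        if sl.max() - sl.min() < 1e-6:
            continue
        t = threshold_otsu(sl, nbins=n_bins)
        binary[:, :, j] = sl > t
    return binary


def filter_clusters(binary: np.ndarray, min_voxels: int = 10) -> np.ndarray:
    """Drop 26-connected components smaller than ``min_voxels`` (boundary kept)."""
    binary = np.asarray(binary).astype(bool)
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return binary.astype(np.uint8)
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_voxels) + 1
    return np.isin(labels, keep).astype(np.uint8)


def detect_centroids(binary: np.ndarray, config: OpticsConfig,
                     source: str = "predicted") -> CentroidSet:
    """One centroid per 26-connected component, in um.

    Voxel (i, j, k) has its center at ((i+0.5) dx, (j+0.5) dy, (k+1) dz_coarse),
    matching the backpropagation slice depths.
    """
    binary = np.asarray(binary).astype(bool)
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return CentroidSet(points_um=np.empty((0, 3)), source=source)
    coms = ndimage.center_of_mass(binary, labels, index=np.arange(1, n + 1))
    coms = np.asarray(coms, dtype=np.float64)
    dx = effective_pixel(config) * 1e-3
    dz = config.backprop_axial_step_um
    points = np.column_stack([
        (coms[:, 0] + 0.5) * dx,
        (coms[:, 1] + 0.5) * dx,
        (coms[:, 2] + 1.0) * dz,
    ])
    return CentroidSet(points_um=points, source=source)


def match_and_classify(predicted: CentroidSet, truth: CentroidSet,
                       gate_um: tuple[float, float, float] = DEFAULT_GATE_UM,
                       anisotropic_cost: bool = False) -> MatchResult:
    """Assignment-based TP/FP/FN labelling.

    A minimum-total-Euclidean-distance one-to-one assignment is solved first
    (unmatched members allowed when set sizes differ); a matched pair is TP
    iff it falls inside the elliptical gate (dx/a)^2 + (dy/b)^2 + (dz/c)^2
    <= 1 with semi-axes a, b, c = half the gate dimensions. Outside-gate
    pairs contribute one FP and one FN. ``anisotropic_cost`` switches the
    assignment metric itself to the gate-normalized distance.
    """
    p = predicted.points_um
    t = truth.points_um
    semi = np.asarray(gate_um, dtype=np.float64) / 2.0
    tp_pairs: list[tuple[int, int]] = []
    matched_p: set[int] = set()
    matched_t: set[int] = set()
    if len(p) and len(t):
        diff = p[:, None, :] - t[None, :, :]
        if anisotropic_cost:
            cost = np.sqrt(np.sum((diff / semi) ** 2, axis=2))
        else:
            cost = np.sqrt(np.sum(diff**2, axis=2))
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            matched_p.add(int(i))
            matched_t.add(int(j))
            d = p[i] - t[j]
            if np.sum((d / semi) ** 2) <= 1.0:
                tp_pairs.append((int(i), int(j)))
    tp_p = {i for i, _ in tp_pairs}
    tp_t = {j for _, j in tp_pairs}
    fp_indices = [i for i in range(len(p)) if i not in tp_p]
    fn_indices = [j for j in range(len(t)) if j not in tp_t]
    return MatchResult(tp_pairs=tp_pairs, fp_indices=fp_indices,
                       fn_indices=fn_indices, predicted=predicted, truth=truth)


def jaccard_index(tp: int, fp: int, fn: int) -> float | None:
    """JI = TP / (TP + FP + FN); ``None`` (flagged null) when all counts are 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    total = tp + fp + fn
    if total == 0:
        return None
    return tp / total


def depthwise_ji(matches: list[MatchResult], config: OpticsConfig,
                 bin_slices: int = 10) -> LocalizationReport:
    """Jaccard index per axial depth bin, mean/std across volumes.

    Bins group ``bin_slices`` coarse slices (50 um at the 5 um spacing). TP
    and FN particles are binned by the ground-truth depth, FP particles by
    the predicted depth. Empty bins are NaN (flagged null).
    """
    dz = config.backprop_axial_step_um
    n_slices = round(config.axial_extent_um / dz)
    n_bins = -(-n_slices // bin_slices)
    edges = np.arange(n_bins + 1) * bin_slices * dz

    def bin_of(depth_um: float) -> int:
        j = int(depth_um // (bin_slices * dz))
        return min(max(j, 0), n_bins - 1)

    per_volume = np.full((len(matches), n_bins), np.nan)
    for v, m in enumerate(matches):
        tp = np.zeros(n_bins, dtype=int)
        fp = np.zeros(n_bins, dtype=int)
        fn = np.zeros(n_bins, dtype=int)
        for i, j in m.tp_pairs:
            tp[bin_of(m.truth.points_um[j, 2])] += 1
        for i in m.fp_indices:
            fp[bin_of(m.predicted.points_um[i, 2])] += 1
        for j in m.fn_indices:
            fn[bin_of(m.truth.points_um[j, 2])] += 1
        for b in range(n_bins):
            ji = jaccard_index(int(tp[b]), int(fp[b]), int(fn[b]))
            if ji is not None:
                per_volume[v, b] = ji
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
        mean = np.nanmean(per_volume, axis=0)
        std = np.nanstd(per_volume, axis=0)
    return LocalizationReport(matches=matches, bin_edges_um=edges,
                              per_volume_bin_ji=per_volume,
                              bin_mean=mean, bin_std=std)


def weight_statistics(alpha_by_condition: dict) -> pd.DataFrame:
    """Component-wise mean/std of the synthesis weights per condition.

    ``alpha_by_condition`` maps a condition label to an (n_samples,
    n_experts) array of alpha vectors (each summing to 1). Returns a tidy
    DataFrame with columns condition, component, mean, std.
    """
    records = []
    for condition, samples in alpha_by_condition.items():
        samples = np.asarray(samples, dtype=np.float64)
        if samples.ndim != 2 or samples.shape[0] == 0:
            raise ValueError(f"condition {condition!r} has no samples")
        if not np.allclose(samples.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"condition {condition!r} has weights not summing to 1")
        mean = samples.mean(axis=0)
        std = samples.std(axis=0)
        for c in range(samples.shape[1]):
            records.append({"condition": condition, "component": c + 1,
                            "mean": float(mean[c]), "std": float(std[c])})
    return pd.DataFrame.from_records(records)
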