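"""Normalization and patch extraction for network training.

Backpropagated volumes enter the network as their amplitude |R|, standardized
over the *whole* volume (never per patch); holograms are standardized over
the whole image the same way. Training patches overlap laterally (stride 64
for 128-pixel patches); validation and test patches do not (stride = patch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormalizedArray",
    "PatchPair",
    "DegenerateInputError",
    "normalize",
    "patch_origins",
    "extract_patches",
    "build_dataset",
]


class DegenerateInputError(ValueError):
    """Raised when an array cannot be standardized (zero variance)."""


@dataclass
class NormalizedArray:
    """A standardized array together with the statistics removed from it."""

    values: np.ndarray
    source_mean: float
    source_std: float


@dataclass
class PatchPair:
    """Laterally co-registered training triple.

    input_subvolume: (px, py, nz) standardized amplitude of the backprop volume
    hologram_patch:  (px, py) standardized hologram (the gating-network input)
    label_subvolume: (px, py, nz) binary ground truth
    origin:          (x0, y0) lateral offset in the parent arrays
    """

    input_subvolume: np.ndarray
    hologram_patch: np.ndarray
    label_subvolume: np.ndarray
    origin: tuple[int, int]


def normalize(array: np.ndarray) -> NormalizedArray:
    """Standardize to zero mean, unit standard deviation.

    Raises :class:`DegenerateInputError` on (near-)constant input rather than
    dividing by ~0.
    """
    array = np.asarray(array, dtype=np.float64)
    mean = float(array.mean())
    std = float(array.std())
    if std < 1e-12:
        raise DegenerateInputError("cannot standardize a constant array")
    return NormalizedArray(values=(array - mean) / std, source_mean=mean, source_std=std)


def patch_origins(image_size: int, patch: int, stride: int) -> list[int]:
    """Regular patch offsets 0, stride, 2*stride, ... with offset+patch <= size.

    Trailing remainders are dropped (floor rule): 1024/128 at stride 64 gives
    15 offsets per dimension.
    """
    if patch > image_size:
        raise ValueError(f"patch {patch} exceeds image size {image_size}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = (image_size - patch) // stride + 1
    return [i * stride for i in range(n)]


def extract_patches(array: np.ndarray, patch: int, stride: int):
    """Yield ((x0, y0), view) for every lateral patch of a 2D or 3D array."""
    xs = patch_origins(array.shape[0], patch, stride)
    ys = patch_origins(array.shape[1], patch, stride)
    for x0 in xs:
        for y0 in ys:
            yield (x0, y0), array[x0:x0 + patch, y0:y0 + patch, ...]


def build_dataset(
    volumes: list[np.ndarray],
    holograms: list[np.ndarray],
    labels: list[np.ndarray],
    patch: int = 128,
    role: str = "train",
    stride: int | None = None,
) -> list[PatchPair]:
    """Assemble co-registered patch pairs from whole volumes.

    ``volumes`` are amplitude volumes (nx, ny, nz), ``holograms`` intensity
    images (nx, ny), ``labels`` binary volumes (nx, ny, nz). Normalization is
    applied per whole volume/hologram *before* patching. The stride defaults
    to patch//2 for training (64 for 128-pixel patches) and to ``patch`` for
    validation/testing; empty (all-background) patches are kept.
    """
    if not (len(volumes) == len(holograms) == len(labels)):
        raise ValueError("volumes, holograms and labels must have equal length")
    if role not in ("train", "val", "test"):
        raise ValueError(f"unknown role {role!r}")
    if stride is None:
        stride = patch // 2 if role == "train" else patch
    pairs: list[PatchPair] = []
    for vol, holo, lab in zip(volumes, holograms, labels):
        if vol.shape[:2] != holo.shape or vol.shape != lab.shape:
            raise ValueError(
                f"shape mismatch: volume {vol.shape}, hologram {holo.shape}, "
                f"label {lab.shape}"
            )
        nvol = normalize(vol).values
        nholo = normalize(holo).values
        vol_patches = extract_patches(nvol, patch, stride)
        holo_patches = extract_patches(nholo, patch, stride)
        lab_patches = extract_patches(lab, patch, stride)
        for (ov, pv), (oh, ph), (ol, pl) in zip(vol_patches, holo_patches, lab_patches):
            assert ov == oh == ol
            pairs.append(PatchPair(
                input_subvolume=np.ascontiguousarray(pv),
                hologram_patch=np.ascontiguousarray(ph),
                label_subvolume=np.ascontiguousarray(pl),
                origin=ov,
            ))
    return pairs
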