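"""Holographic backpropagation: hologram -> complex 3D volume.

The recorded intensity is numerically propagated backwards from the hologram
plane into the sample, slice by slice, with the angular-spectrum (Weyl) form
of the free-space Green's-function transfer kernel. This is the minimum-norm
linear estimate of the 3D scattering potential under the first Born
approximation, and is the raw input to the descattering network.

Slice j (1-based) lies a depth ``j * backprop_axial_step`` before the
hologram plane, so the slices tile (0, axial_extent] shallow to deep
(slice 1 nearest the hologram plane = exit face of the volume).
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .bpm import Hologram, angular_spectrum_kernel
from .optics import OpticsConfig, effective_pixel, grid_dimensions

__all__ = ["BackpropVolume", "greens_transfer_kernel", "backpropagate"]


@dataclass
class BackpropVolume:
    """Complex reconstruction R(x, y; z) on the coarse axial grid."""

    values: np.ndarray  # (nx, ny, n_coarse_z) complex
    slice_depths_um: np.ndarray  # depth of each slice below the hologram plane

    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("real", data=self.values.real)
            fh.create_dataset("imag", data=self.values.imag)
            fh.attrs["slice_depths_um"] = self.slice_depths_um

    @classmethod
    def from_hdf5(cls, path) -> "BackpropVolume":
        with h5py.File(path, "r") as fh:
            values = fh["real"][...] + 1j * fh["imag"][...]
            depths = np.asarray(fh.attrs["slice_depths_um"])
        return cls(values=values, slice_depths_um=depths)


def greens_transfer_kernel(nx: int, ny: int, z_um: float,
                           config: OpticsConfig) -> np.ndarray:
    """Backward-propagation kernel H(u, v; z) for depth z behind the hologram.

    The analytic angular-spectrum form of the Green's-function transfer
    kernel, conjugated to reverse the propagation direction: unit modulus on
    the propagating band, zero outside.
    """
    if z_um < 0:
        raise ValueError("depth must be nonnegative")
    pitch = effective_pixel(config) * 1e-3
    lam_m = config.wavelength_medium_nm * 1e-3
    forward = angular_spectrum_kernel(nx, ny, pitch, z_um, lam_m)
    return np.conj(forward)


def backpropagate(hologram: Hologram, config: OpticsConfig) -> BackpropVolume:
    """Backpropagate a hologram into ``n_coarse_z`` complex slices.

    slice_j = IFFT( FFT(I) * H(u, v; z_j) ) at z_j = j * backprop step,
    j = 1..n_coarse_z, ordered shallow to deep.
    """
    nx, ny, _, n_coarse = grid_dimensions(config)
    intensity = np.asarray(hologram.intensity, dtype=np.float64)
    if intensity.shape != (nx, ny):
        raise ValueError(
            f"hologram shape {intensity.shape} does not match grid ({nx}, {ny})"
        )
    spectrum = np.fft.fft2(intensity)
    dz = config.backprop_axial_step_um
    depths = (np.arange(1, n_coarse + 1)) * dz
    volume = np.empty((nx, ny, n_coarse), dtype=np.complex128)
    for j, z in enumerate(depths):
        kernel = greens_transfer_kernel(nx, ny, float(z), config)
        volume[:, :, j] = np.fft.ifft2(spectrum * kernel)
    return BackpropVolume(values=volume, slice_depths_um=depths)
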