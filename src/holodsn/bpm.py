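"""Split-step beam-propagation forward model for inline holograms.

A unit-amplitude plane wave enters the volume; at each fine axial slice the
field is multiplied by a thin phase screen carrying the local index contrast
and then diffracted to the next slice with the angular-spectrum transfer
function of the homogeneous medium. Multiple scattering emerges naturally
from the alternation. The hologram is the intensity at the exit face of the
volume (idealized hologram plane).

Conventions fixed here:

* The phase screen advances the phase by k0 * dn * dz with k0 the vacuum
  wavenumber — the index contrast is relative to the medium, and background
  propagation through the medium is carried by the angular-spectrum kernel
  at lambda_m.
* Evanescent spatial frequencies (u^2 + v^2 > 1/lambda_m^2) are zeroed.
* FFT wrap-around is controlled by an integer zero-padding factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from .optics import OpticsConfig, effective_pixel
from .scene import IndexVolume

__all__ = ["ComplexField", "Hologram", "angular_spectrum_propagate", "simulate_hologram"]


@dataclass
class ComplexField:
    """Monochromatic scalar field on the lateral grid at one axial plane."""

    values: np.ndarray  # (nx, ny) complex
    plane_z_um: float
    config: OpticsConfig


@dataclass
class Hologram:
    """Recorded (or simulated) intensity image |E|^2 at the hologram plane."""

    intensity: np.ndarray  # (nx, ny) float, >= 0
    provenance: str = "simulated"  # or "measured"
    condition: dict | None = None  # e.g. {"density_per_ul": ..., "dn": ..., "d_um": ...}

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.intensity.astype(np.float32))

    @classmethod
    def from_tiff(cls, path, provenance: str = "measured") -> "Hologram":
        return cls(intensity=np.asarray(tifffile.imread(path), dtype=np.float64),
                   provenance=provenance)


def _frequency_grids(nx: int, ny: int, pitch_um: float):
    u = np.fft.fftfreq(nx, d=pitch_um)  # cycles / um
    v = np.fft.fftfreq(ny, d=pitch_um)
    return u[:, None], v[None, :]


def angular_spectrum_kernel(nx: int, ny: int, pitch_um: float,
                            distance_um: float, lambda_medium_um: float) -> np.ndarray:
    """exp(i 2 pi z sqrt(1/lambda_m^2 - u^2 - v^2)) on the propagating band.

    Negative distances use the conjugate kernel; evanescent components are 0.
    """
    u, v = _frequency_grids(nx, ny, pitch_um)
    arg = 1.0 / lambda_medium_um**2 - u * u - v * v
    band = arg > 0
    kz = np.sqrt(np.where(band, arg, 0.0))
    kernel = np.exp(2j * np.pi * distance_um * kz)
    return np.where(band, kernel, 0.0)


def angular_spectrum_propagate(field: ComplexField, distance_um: float,
                               config: OpticsConfig, pad_factor: int = 1) -> ComplexField:
    """Free-space (in-medium) propagation of a 2D field by ``distance_um``."""
    values = np.asarray(field.values, dtype=np.complex128)
    nx, ny = values.shape
    pitch = effective_pixel(config) * 1e-3
    lam_m = config.wavelength_medium_nm * 1e-3
    if pad_factor > 1:
        padded = np.zeros((nx * pad_factor, ny * pad_factor), dtype=np.complex128)
        padded[:nx, :ny] = values
        values = padded
    kernel = angular_spectrum_kernel(*values.shape, pitch, distance_um, lam_m)
    out = np.fft.ifft2(np.fft.fft2(values) * kernel)
    if pad_factor > 1:
        out = out[:nx, :ny]
    return ComplexField(values=out, plane_z_um=field.plane_z_um + distance_um,
                        config=config)


def simulate_hologram(volume: IndexVolume, config: OpticsConfig,
                      noise_std: float = 0.0, noise_seed: int | None = None,
                      pad_factor: int = 2) -> Hologram:
    """Propagate a plane wave through the index volume and record |E|^2.

    Split-step loop: phase screen (vacuum wavenumber times the slice's index
    contrast integrated over the fine step), then angular-spectrum diffraction
    by one fine step in the medium. After the last slice the field sits at the
    exit face, which is the hologram plane. Optional additive Gaussian noise
    is clamped at zero.
    """
    values = volume.values
    nx, ny, n_fine = values.shape
    pitch = effective_pixel(config) * 1e-3
    lam_m = config.wavelength_medium_nm * 1e-3
    dz = config.fine_axial_step_nm * 1e-3
    k0_dz = 2.0 * np.pi / (config.wavelength_nm * 1e-3) * dz  # vacuum k times dz

    px, py = nx * pad_factor, ny * pad_factor
    field = np.ones((px, py), dtype=np.complex128)
    kernel = angular_spectrum_kernel(px, py, pitch, dz, lam_m)
    for j in range(n_fine):
        slab = values[:, :, j]
        if np.any(slab):
            phase = np.zeros((px, py))
            phase[:nx, :ny] = k0_dz * slab
            field = field * np.exp(1j * phase)
        field = np.fft.ifft2(np.fft.fft2(field) * kernel)
    intensity = np.abs(field[:nx, :ny]) ** 2
    if noise_std > 0:
        rng = np.random.default_rng(noise_seed)
        intensity = np.clip(intensity + rng.normal(0.0, noise_std, intensity.shape), 0.0, None)
    return Hologram(intensity=intensity, provenance="simulated")
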