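"""Imaging-system geometry and physical unit conversions.

Every other module derives its grids from :class:`OpticsConfig`: the fine
axial grid used by the beam-propagation forward model, the coarse axial grid
used by holographic backpropagation and the network, and the lateral pixel
raster shared by holograms and volumes.

Units: lengths carry an explicit unit suffix in the field name. Internally
nanometres are used for sub-micron steps and micrometres for extents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import yaml

__all__ = [
    "OpticsConfig",
    "InvalidConfigError",
    "effective_pixel",
    "lateral_resolution",
    "axial_resolution",
    "grid_dimensions",
    "full_scale_config",
    "mini_config",
]


class InvalidConfigError(ValueError):
    """Raised when an OpticsConfig violates a physical or sampling constraint."""


@dataclass(frozen=True)
class OpticsConfig:
    """Parameters of the inline holographic imaging system.

    Attributes
    ----------
    wavelength_nm:
        Vacuum wavelength of the (coherent) illumination.
    medium_index:
        Refractive index of the immersion medium (water = 1.33).
    numerical_aperture:
        NA of the imaging objective; must satisfy 0 < NA < medium_index.
    magnification:
        Lateral magnification of the relay onto the sensor.
    sensor_pixel_um:
        Physical sensor pixel pitch.
    lateral_extent_x_um, lateral_extent_y_um:
        Lateral size of the imaged volume (= field of view at the sample).
    axial_extent_um:
        Depth of the imaged volume.
    fine_axial_step_nm:
        Slice spacing of the beam-propagation forward model (~ lambda_m / 4).
    backprop_axial_step_um:
        Slice spacing of the backpropagated reconstruction (~ axial resolution).
    lateral_pixels_x, lateral_pixels_y:
        Number of sensor pixels used along x and y.
    """

    wavelength_nm: float = 632.8
    medium_index: float = 1.33
    numerical_aperture: float = 0.4
    magnification: float = 20.0
    sensor_pixel_um: float = 3.45
    lateral_extent_x_um: float = 176.64
    lateral_extent_y_um: float = 176.64
    axial_extent_um: float = 500.0
    fine_axial_step_nm: float = 118.4
    backprop_axial_step_um: float = 5.0
    lateral_pixels_x: int = 1024
    lateral_pixels_y: int = 1024

    def __post_init__(self) -> None:
        if self.magnification <= 0:
            raise InvalidConfigError("magnification must be positive")
        if not 0 < self.numerical_aperture < self.medium_index:
            raise InvalidConfigError(
                "numerical aperture must lie in (0, medium_index); got "
                f"NA={self.numerical_aperture}, n={self.medium_index}"
            )
        for name in (
            "wavelength_nm",
            "lateral_extent_x_um",
            "lateral_extent_y_um",
            "axial_extent_um",
            "fine_axial_step_nm",
            "backprop_axial_step_um",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.fine_axial_step_nm > self.axial_extent_um * 1e3:
            raise InvalidConfigError("fine axial step exceeds axial extent")
        if self.backprop_axial_step_um > self.axial_extent_um:
            raise InvalidConfigError("backprop axial step exceeds axial extent")
        # Effective pixel must tile the stated field of view.
        eff_um = self.sensor_pixel_um / self.magnification
        for extent, npix in (
            (self.lateral_extent_x_um, self.lateral_pixels_x),
            (self.lateral_extent_y_um, self.lateral_pixels_y),
        ):
            if abs(extent / npix - eff_um) > 1e-3 * eff_um:
                raise InvalidConfigError(
                    "lateral extent / pixel count inconsistent with "
                    "sensor_pixel / magnification"
                )
        # Depth sampling of the forward model must resolve lambda_m / 4
        # (1% slack covers the conventional 118.4 nm value for water).
        nyquist_nm = self.wavelength_nm / (4.0 * self.medium_index)
        if self.fine_axial_step_nm > nyquist_nm * 1.01:
            raise InvalidConfigError(
                f"fine axial step {self.fine_axial_step_nm} nm violates the "
                f"quarter-wavelength depth sampling rule ({nyquist_nm:.2f} nm)"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def wavelength_medium_nm(self) -> float:
        """Wavelength in the immersion medium, lambda_m = lambda / n."""
        return self.wavelength_nm / self.medium_index

    @property
    def wavenumber_per_um(self) -> float:
        """k = 2 pi / lambda_m, in rad/um."""
        return 2.0 * math.pi / (self.wavelength_medium_nm * 1e-3)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "OpticsConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def replace(self, **kwargs) -> "OpticsConfig":
        return replace(self, **kwargs)


def effective_pixel(config: OpticsConfig) -> float:
    """Effective lateral pixel size at the sample, in nm.

    Demagnifies the sensor pitch: 3.45 um at 20x gives 172.5 nm.
    """
    return config.sensor_pixel_um * 1e3 / config.magnification


def lateral_resolution(config: OpticsConfig) -> float:
    """Diffraction-limited lateral resolution lambda_m / NA, in um."""
    return (config.wavelength_nm / config.medium_index) * 1e-3 / config.numerical_aperture


def axial_resolution(config: OpticsConfig) -> float:
    """Axial resolution lambda_m / (1 - sqrt(1 - NA^2)), in um."""
    na = config.numerical_aperture
    if not 0 < na < 1:
        raise InvalidConfigError("axial resolution requires 0 < NA < 1")
    lam_m_um = (config.wavelength_nm / config.medium_index) * 1e-3
    return lam_m_um / (1.0 - math.sqrt(1.0 - na * na))


def grid_dimensions(config: OpticsConfig) -> tuple[int, int, int, int]:
    """Voxel counts (nx, ny, n_fine_z, n_coarse_z) of the two axial grids.

    The fine axial count uses floor (500 um / 118.4 nm -> 4222 slices); the
    coarse count uses round (500 um / 5 um -> 100 slices).
    """
    eff_um = effective_pixel(config) * 1e-3
    nx = round(config.lateral_extent_x_um / eff_um)
    ny = round(config.lateral_extent_y_um / eff_um)
    n_fine_z = math.floor(config.axial_extent_um * 1e3 / config.fine_axial_step_nm)
    n_coarse_z = round(config.axial_extent_um / config.backprop_axial_step_um)
    return nx, ny, n_fine_z, n_coarse_z


def full_scale_config() -> OpticsConfig:
    """Full-scale experimental geometry (1024 x 1024 x 4222 fine voxels)."""
    return OpticsConfig()


def mini_config() -> OpticsConfig:
    """Small geometry for CPU-scale runs: 128 x 128 x 20 coarse voxels.

    A 6.9x relay gives a 0.5 um effective pixel (still Nyquist for NA 0.4 in
    water), so 128 pixels span 64 um laterally. The fine step stays at the
    water quarter-wavelength value; the coarse step stays at 5 um, giving 20
    backpropagation slices over the 100 um depth.
    """
    return OpticsConfig(
        magnification=6.9,
        sensor_pixel_um=3.45,
        lateral_extent_x_um=64.0,
        lateral_extent_y_um=64.0,
        axial_extent_um=100.0,
        fine_axial_step_nm=118.4,
        backprop_axial_step_um=5.0,
        lateral_pixels_x=128,
        lateral_pixels_y=128,
    )
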