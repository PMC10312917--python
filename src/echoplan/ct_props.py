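"""Hounsfield-unit volumes to heterogeneous acoustic property maps.

CT attenuation is mapped to sound speed, density and absorption through a
porosity intermediate: HU are clamped to [0, hu_max] and scaled to a bone
volume fraction, and each acoustic property interpolates linearly between
its water and dense-bone endpoint.  Absorption is reported in dB/cm at a
reference frequency with a frequency power-law exponent of two, the usual
narrowband description of skull absorption around 250 kHz.

All endpoints are configurable through :class:`ConversionParams`; swapping
in alternative piecewise-polynomial coefficients is a configuration change,
not a code change.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import ndimage

from .volume import VoxelVolume

__all__ = [
    "ConversionParams",
    "AcousticMediumMap",
    "hu_to_porosity",
    "porosity_to_props",
    "absorption_map",
    "build_medium",
]


@dataclass(frozen=True)
class ConversionParams:
    """Endpoints of the HU -> acoustic-property conversion.

    Water values are at room temperature; bone values are representative of
    dense cranial bone and deliberately exposed as configuration, since the
    conversion's qualitative (linear-in-porosity) form matters more than
    any particular endpoint.
    """

    hu_max: float = 1000.0
    c_water: float = 1500.0  # m/s
    c_bone: float = 3000.0  # m/s
    rho_water: float = 1000.0  # kg/m^3
    rho_bone: float = 2200.0  # kg/m^3
    alpha_water: float = 0.0022  # dB/cm at f_ref
    alpha_bone_max: float = 0.68  # dB/cm at f_ref
    f_ref: float = 250e3  # Hz
    power_law_exponent: float = 2.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "ConversionParams":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class AcousticMediumMap:
    """Co-registered sound-speed, density and absorption maps.

    Arrays may be 2D (planar simulations) or 3D; ``spacing`` has one entry
    per array axis, in mm.  Absorption is dB/cm at ``f_ref`` with the given
    power-law exponent.
    """

    sound_speed: np.ndarray  # m/s
    density: np.ndarray  # kg/m^3
    absorption: np.ndarray  # dB/cm at f_ref
    spacing: tuple  # mm
    f_ref: float = 250e3
    power_law_exponent: float = 2.0

    def __post_init__(self):
        self.sound_speed = np.asarray(self.sound_speed, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        self.absorption = np.asarray(self.absorption, dtype=float)
        if not (self.sound_speed.shape == self.density.shape == self.absorption.shape):
            raise ValueError("property maps must share one shape")
        if len(self.spacing) != self.sound_speed.ndim:
            raise ValueError("spacing must have one entry per array axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def ndim(self) -> int:
        return self.sound_speed.ndim

    @classmethod
    def homogeneous_water(cls, shape, spacing, params: ConversionParams = ConversionParams()):
        """Uniform free-field (water) medium."""
        shape = tuple(shape)
        return cls(
            np.full(shape, params.c_water),
            np.full(shape, params.rho_water),
            np.full(shape, params.alpha_water),
            tuple(spacing),
            f_ref=params.f_ref,
            power_law_exponent=params.power_law_exponent,
        )

    def save(self, prefix) -> None:
        """Write the three maps as NIfTI volumes (3D media only)."""
        if self.ndim != 3:
            raise ValueError("NIfTI export supports 3D media only")
        for name, arr in (
            ("sound_speed", self.sound_speed),
            ("density", self.density),
            ("absorption", self.absorption),
        ):
            VoxelVolume(arr.astype(np.float32), self.spacing).save(f"{prefix}_{name}.nii")


def hu_to_porosity(hu, hu_max: float = 1000.0):
    """Porosity (water volume fraction) from HU: 1 at water, 0 at dense bone.

    Out-of-range HU (air, fat, metal) are clamped to [0, hu_max] rather
    than extrapolated.
    """
    hu = np.asarray(hu, dtype=float)
    if not np.isfinite(hu).all():
        raise ValueError("non-finite HU values")
    return 1.0 - np.clip(hu, 0.0, hu_max) / hu_max


def porosity_to_props(phi, params: ConversionParams = ConversionParams()):
    """Density (kg/m^3) and sound speed (m/s) from porosity, both linear in
    the bone fraction (1 - phi)."""
    phi = np.asarray(phi, dtype=float)
    if ((phi < 0) | (phi > 1)).any():
        raise ValueError("porosity must lie in [0, 1]")
    rho = phi * params.rho_water + (1.0 - phi) * params.rho_bone
    c = params.c_water + (params.c_bone - params.c_water) * (1.0 - phi)
    return rho, c


def absorption_map(phi, params: ConversionParams = ConversionParams()):
    """Absorption (dB/cm at f_ref) linear in the bone fraction, from the
    water floor up to the stated bone maximum."""
    phi = np.asarray(phi, dtype=float)
    if ((phi < 0) | (phi > 1)).any():
        raise ValueError("porosity must lie in [0, 1]")
    return params.alpha_water + (params.alpha_bone_max - params.alpha_water) * (1.0 - phi)


def build_medium(
    hu_volume: VoxelVolume,
    target_spacing: float,
    params: ConversionParams = ConversionParams(),
) -> AcousticMediumMap:
    """Resample an HU volume to an isotropic simulation grid and convert it
    voxelwise into an acoustic medium.

    Resampling is trilinear (HU are resampled, then converted, matching the
    usual practice of regridding CT before property conversion).
    """
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    zoom = np.asarray(hu_volume.spacing) / float(target_spacing)
    hu = ndimage.zoom(np.asarray(hu_volume.data, dtype=float), zoom, order=1, mode="nearest")
    phi = hu_to_porosity(hu, params.hu_max)
    rho, c = porosity_to_props(phi, params)
    alpha = absorption_map(phi, params)
    sp = (float(target_spacing),) * hu.ndim
    return AcousticMediumMap(c, rho, alpha, sp, f_ref=params.f_ref, power_law_exponent=params.power_law_exponent)


def medium_from_hu_array(hu: np.ndarray, spacing, params: ConversionParams = ConversionParams()) -> AcousticMediumMap:
    """Convert an HU array already on the simulation grid (any dimensionality)."""
    phi = hu_to_porosity(hu, params.hu_max)
    rho, c = porosity_to_props(phi, params)
    alpha = absorption_map(phi, params)
    return AcousticMediumMap(c, rho, alpha, tuple(spacing), f_ref=params.f_ref, power_law_exponent=params.power_law_exponent)
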