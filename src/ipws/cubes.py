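"""Image-cube data model: acquisition metadata and temporal/spectral cubes.

A *temporal cube* ``I(t, y, x)`` is a stack of wide-field backscattered
images acquired at one wavelength over time; a *spectral cube*
``I(lambda, y, x)`` is the same field of view scanned across wavelengths
(500-700 nm).  Both carry an :class:`AcquisitionMeta` holding the physical
parameters every downstream equation needs, most importantly the optical
wavenumber in the sample medium, ``k = 2*pi*n / lambda`` (um^-1): the
backscattering geometry doubles the phase sensitivity (phase = 2 k z),
which is where the ``4 k^2`` factor of the diffusion relation comes from.

Axis order is ``(t | lambda, y, x)`` with 0-based indices; frame timestamps
are ``frame_index * frame_interval`` with intensity attributed to the start
of the exposure window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "AcquisitionMeta",
    "TemporalCube",
    "SpectralCube",
    "ReferenceCube",
    "CubeFormatError",
    "CubeMetadataError",
    "normalize_cube",
    "wavenumber",
]


class CubeFormatError(ValueError):
    """Cube data violates the shape/axis/value contract."""


class CubeMetadataError(ValueError):
    """Acquisition metadata is missing or inconsistent."""


def wavenumber(wavelength_nm: float, medium_refractive_index: float) -> float:
    """Optical wavenumber in the medium, um^-1.

    Uses the medium convention ``k = 2*pi*n / lambda_vacuum``: the physically
    correct phase rate for light propagating (and backscattering) inside the
    sample.  Recorded in every output manifest because the diffusion
    coefficient scales as ``1/k^2``.
    """
    return 2.0 * math.pi * medium_refractive_index / (wavelength_nm * 1e-3)


@dataclass(frozen=True)
class AcquisitionMeta:
    """Physical acquisition parameters shared by all cube analyses.

    Parameters
    ----------
    wavelengths
        Vacuum wavelengths in nm.  Exactly one for a temporal cube, three or
        more (strictly increasing, within 500-700 nm by convention) for a
        spectral cube.
    exposure_time
        Camera integration time per frame, seconds.
    frame_interval
        Time between frame starts, seconds (``>= exposure_time``).
    n_frames
        Number of frames (or wavelengths) in the cube.
    pixel_size
        Lateral sampling in the object plane, um per pixel.
    medium_refractive_index
        Refractive index of the sample medium (cells/media ~1.33-1.46,
        phantom glycerol mixtures 1.44-1.46).
    """

    wavelengths: tuple
    exposure_time: float
    frame_interval: float
    n_frames: int
    pixel_size: float
    medium_refractive_index: float
    illumination_na: float = 0.55
    collection_na: float = 1.4

    def __post_init__(self):
        object.__setattr__(self, "wavelengths", tuple(float(w) for w in self.wavelengths))
        self.validate()

    def validate(self) -> None:
        if not self.wavelengths:
            raise CubeMetadataError("at least one wavelength is required")
        if any(not (400.0 <= w <= 800.0) for w in self.wavelengths):
            raise CubeMetadataError(
                f"wavelengths must lie within 400-800 nm, got {self.wavelengths}"
            )
        if self.exposure_time <= 0 or self.frame_interval <= 0:
            raise CubeMetadataError("exposure_time and frame_interval must be positive")
        if self.exposure_time > self.frame_interval * (1 + 1e-12):
            raise CubeMetadataError(
                f"exposure_time ({self.exposure_time}) exceeds frame_interval "
                f"({self.frame_interval})"
            )
        if self.n_frames < 1:
            raise CubeMetadataError("n_frames must be >= 1")
        if self.pixel_size <= 0:
            raise CubeMetadataError("pixel_size must be positive")
        if self.medium_refractive_index < 1.0:
            raise CubeMetadataError("medium_refractive_index must be >= 1")

    @property
    def acquisition_time(self) -> float:
        """Total acquisition span Delta-T = n_frames * frame_interval, s."""
        return self.n_frames * self.frame_interval

    @property
    def wavelength(self) -> float:
        """The single imaging wavelength (nm); errors on spectral metadata."""
        if len(self.wavelengths) != 1:
            raise CubeMetadataError("meta has multiple wavelengths; use .wavelengths")
        return self.wavelengths[0]

    @property
    def wavenumber(self) -> float:
        """k = 2*pi*n/lambda in um^-1 at the (single) imaging wavelength."""
        return wavenumber(self.wavelength, self.medium_refractive_index)

    @property
    def wavenumbers(self) -> np.ndarray:
        """k per wavelength, um^-1 (spectral cubes)."""
        return np.array(
            [wavenumber(w, self.medium_refractive_index) for w in self.wavelengths]
        )

    def replace(self, **kw) -> "AcquisitionMeta":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "wavelengths": list(self.wavelengths),
            "exposure_time": self.exposure_time,
            "frame_interval": self.frame_interval,
            "n_frames": self.n_frames,
            "pixel_size": self.pixel_size,
            "medium_refractive_index": self.medium_refractive_index,
            "illumination_na": self.illumination_na,
            "collection_na": self.collection_na,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        required = {
            "wavelengths",
            "exposure_time",
            "frame_interval",
            "n_frames",
            "pixel_size",
            "medium_refractive_index",
        }
        missing = required - set(d)
        if missing:
            raise CubeMetadataError(f"missing metadata fields: {sorted(missing)}")
        known = required | {"illumination_na", "collection_na"}
        return cls(**{k: d[k] for k in d if k in known})


def _validate_intensities(intensities: np.ndarray, n_leading: int) -> np.ndarray:
    arr = np.asarray(intensities, dtype=np.float64)
    if arr.ndim != 3:
        raise CubeFormatError(f"cube must be 3-D (t|lambda, y, x), got shape {arr.shape}")
    if arr.shape[0] != n_leading:
        raise CubeFormatError(
            f"leading axis length {arr.shape[0]} does not match metadata "
            f"frame/wavelength count {n_leading}; axis order must be (t|lambda, y, x)"
        )
    if not np.all(np.isfinite(arr)):
        raise CubeFormatError("cube intensities must be finite")
    return arr


@dataclass
class TemporalCube:
    """Time series of reflectance images at a single wavelength.

    ``intensities`` has axes ``(t, y, x)``; values are dimensionless
    reflectance once :func:`normalize_cube` has been applied (the phantom
    simulator emits reflectance directly).
    """

    intensities: np.ndarray
    meta: AcquisitionMeta
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.meta.wavelengths) != 1:
            raise CubeMetadataError("TemporalCube requires exactly one wavelength")
        if self.meta.n_frames < 2:
            raise CubeMetadataError("TemporalCube requires n_frames >= 2")
        self.intensities = _validate_intensities(self.intensities, self.meta.n_frames)

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def spatial_shape(self) -> tuple:
        return self.intensities.shape[1:]

    @property
    def timestamps(self) -> np.ndarray:
        """Start-of-exposure times, s."""
        return np.arange(self.n_frames) * self.meta.frame_interval

    @property
    def kind(self) -> str:
        return "temporal"


@dataclass
class SpectralCube:
    """Wavelength scan of reflectance images, axes ``(lambda, y, x)``."""

    intensities: np.ndarray
    meta: AcquisitionMeta
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = self.meta.wavelengths
        if len(wl) < 3:
            raise CubeMetadataError("SpectralCube requires >= 3 wavelengths")
        if not all(b > a for a, b in zip(wl, wl[1:])):
            raise CubeMetadataError("spectral wavelengths must be strictly increasing")
        self.intensities = _validate_intensities(self.intensities, len(wl))

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array(self.meta.wavelengths)

    @property
    def spatial_shape(self) -> tuple:
        return self.intensities.shape[1:]

    @property
    def kind(self) -> str:
        return "spectral"


class ReferenceCube(TemporalCube):
    """Temporal cube acquired from an empty field of view.

    Used to estimate the instrument-noise contribution (LED fluctuations,
    shot/read noise) that is subtracted from sample dynamics measurements.
    """

    @property
    def is_reference(self) -> bool:
        return True

    @property
    def kind(self) -> str:
        return "reference"


def normalize_cube(
    raw_cube,
    dark_frame=None,
    led_reference=None,
    exposure_time: float | None = None,
):
    """Convert raw camera counts to dimensionless reflectance.

    Per pixel and frame: ``(raw - dark) / (led_reference * exposure_time)``.
    Missing dark/LED references default to ``dark=0``, ``led=1`` (with a
    warning) so that simulator-produced cubes, already in reflectance units,
    pass through unchanged.  Raw counts are assumed linear in photon flux.
    """
    cube = raw_cube
    spatial = cube.intensities.shape[1:]
    if exposure_time is None:
        exposure_time = cube.meta.exposure_time
    if exposure_time <= 0:
        raise CubeMetadataError("exposure_time must be positive")

    if dark_frame is None:
        dark = np.zeros(spatial)
        warnings.warn("no dark frame supplied; assuming dark counts = 0", stacklevel=2)
    else:
        dark = np.asarray(dark_frame, dtype=np.float64)
    if led_reference is None:
        led = np.ones(spatial) / exposure_time  # cancels the exposure division
        warnings.warn(
            "no LED reference supplied; assuming unit illumination", stacklevel=2
        )
    else:
        led = np.asarray(led_reference, dtype=np.float64)

    n_lead = cube.intensities.shape[0]
    if dark.shape != spatial or led.shape not in (spatial, (n_lead,) + spatial):
        raise CubeFormatError(
            f"dark/LED reference shape must match spatial shape {spatial} "
            f"(or (n_frames,)+spatial for a per-frame LED reference)"
        )
    if np.any(led == 0):
        raise ZeroDivisionError("led_reference contains zeros; cannot normalize")

    out = (cube.intensities - dark) / (led * exposure_time)
    prov = dict(cube.provenance)
    prov["normalization"] = {
        "dark_frame": dark_frame is not None,
        "led_reference": led_reference is not None,
        "exposure_time": exposure_time,
    }
    return type(cube)(intensities=out, meta=cube.meta, provenance=prov)
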