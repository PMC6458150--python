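"""Spectral-interference structure maps (Sigma_s).

Sigma_s is the per-pixel standard deviation of the spectral interference
signal over the scanned wavelength range (500-700 nm).  It quantifies the
heterogeneity of nanoscale mass-density organization: internal scatterers
at different depths imprint wavelength-dependent oscillations on the
interference with the substrate reflection, and the residual spread of the
spectrum after detrending grows with the amplitude of those oscillations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cubes import SpectralCube

__all__ = ["StructureMap", "compute_sigma_s", "sigma_s_roi_summary"]


@dataclass
class StructureMap:
    """Per-pixel Sigma_s with validity mask and processing provenance."""

    sigma_s: np.ndarray
    valid_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def spatial_shape(self):
        return self.sigma_s.shape


def compute_sigma_s(spectral_cube: SpectralCube, detrend_mode: str = "mean") -> StructureMap:
    """Standard deviation of the detrended spectrum at each pixel.

    ``detrend_mode="mean"`` subtracts the per-pixel spectral mean;
    ``"linear"`` additionally removes a per-pixel linear reflectance slope
    in wavelength before taking the standard deviation.  The population
    convention (divide by the number of wavelengths) is used; both choices
    are recorded in the provenance.
    """
    data = spectral_cube.intensities
    wl = spectral_cube.wavelengths
    if np.nanmax(data) > 2.0:
        warnings.warn(
            "spectral cube does not look normalized to reflectance "
            "(max intensity > 2)", stacklevel=2)

    nan_pixels = np.isnan(data).all(axis=0)
    if detrend_mode == "mean":
        resid = data - data.mean(axis=0, keepdims=True)
    elif detrend_mode == "linear":
        x = wl - wl.mean()
        flat = data.reshape(len(wl), -1)
        coef = np.polynomial.polynomial.polyfit(x, flat, 1)
        fit = np.polynomial.polynomial.polyval(x, coef).T
        resid = (flat - fit).reshape(data.shape)
    else:
        raise ValueError(f"unknown detrend_mode {detrend_mode!r}")

    sigma = np.sqrt(np.mean(resid**2, axis=0))  # population std over lambda
    valid = ~nan_pixels & np.isfinite(sigma)
    return StructureMap(
        sigma_s=np.where(valid, sigma, np.nan), valid_mask=valid,
        provenance={
            "detrend_mode": detrend_mode,
            "std_convention": "population (divide by N_lambda)",
            "wavelength_range_nm": (float(wl[0]), float(wl[-1])),
            "n_wavelengths": int(len(wl)),
        })


def sigma_s_roi_summary(structure_map: StructureMap, mask: np.ndarray):
    """Mean, SEM and pixel count of Sigma_s over valid pixels in ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    sel = mask & structure_map.valid_mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError("mask selects no valid pixels")
    vals = structure_map.sigma_s[sel]
    sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(vals.mean()), sem, n
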