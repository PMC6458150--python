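"""Temporal-interference dynamics: Sigma_t^2, fractional moving mass, and D.

The temporal interference signal at one pixel, ``deltaI(t)`` (reflectance
minus its temporal mean), carries two complementary quantities:

* its variance over the acquisition, ``Sigma_t^2``, is proportional to the
  *fractional moving mass* ``m_f = m_c * Phi`` -- the mass of the typical
  moving macromolecular cluster times the volume fraction of mobile mass;
* the decay rate of its autocorrelation function gives the diffusion
  coefficient through ``B(tau)/B(0) = exp(-4 k^2 D tau)``, i.e.
  ``D = 1 / (4 k^2 t_c)`` with ``t_c`` the correlation time and ``k`` the
  wavenumber in the medium (backscattering doubles the optical phase,
  hence the factor 4 k^2).

The whole-field estimator follows an eleven-step sequence: normalize,
subtract the temporal mean, per-pixel ACF, SNR filtering against a
background (empty-field) ACF, subtraction of the mean background ACF,
per-pixel normalization to one at lag zero, aggregation across pixels
(arithmetic mean of the normalized ACFs by default; see
:func:`estimate_D_mean` for the log-average alternative), truncation at
the first non-positive value, a two-point slope of the log of the mean
ACF, and division by ``-4 k^2``.  The map path replaces cross-pixel
aggregation with a per-lag spatial Gaussian filter.

Slope convention
----------------
By default the decay slope is taken between the first two *nonzero* lags.
Lag zero of the measured ACF is inflated by detector-noise variance and
attenuated by finite-exposure integration, both of which leave lags
``>= tau_1`` untouched up to a common multiplicative factor (for exposure
equal to the frame interval the boxcar average multiplies every lag
``m >= 1`` by the same constant); the slope between lags 1 and 2 is
therefore an unbiased estimate of ``-1/t_c`` without any exposure
correction, which cannot be said of the 0->1 slope.  Set
``slope_lags=(0, 1)`` to use the lag-zero point instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .cubes import AcquisitionMeta, CubeFormatError, ReferenceCube, TemporalCube

__all__ = [
    "AutocorrelationResult",
    "FluctuationTrace",
    "DynamicsMaps",
    "SigmaT2Map",
    "EstimationError",
    "acf_cube",
    "temporal_acf",
    "background_acf",
    "compute_sigma_t2",
    "exposure_correction",
    "exposure_attenuation_factor",
    "fractional_moving_mass",
    "snr_filter",
    "estimate_D_mean",
    "estimate_D_map",
    "compute_dynamics_maps",
    "sensitivity_range",
]

SNR_THRESHOLD = math.sqrt(2.0)


class EstimationError(RuntimeError):
    """No valid pixels (or no usable decay) for the requested estimate."""


# ---------------------------------------------------------------------------
# autocorrelation


def acf_cube(delta: np.ndarray, n_lags: int | None = None) -> np.ndarray:
    """Biased (1/N) autocovariance per pixel via zero-padded FFT.

    ``delta`` has axes (t, y, x) and must be temporally mean-subtracted.
    Returns an array of shape (n_lags, y, x) with ``acf[0]`` equal to the
    population variance.
    """
    n = delta.shape[0]
    if n < 4:
        raise ValueError("need at least 4 frames for an autocorrelation")
    if n_lags is None:
        n_lags = n
    nfft = sp_fft.next_fast_len(2 * n)
    spec = sp_fft.rfft(delta, nfft, axis=0)
    acov = sp_fft.irfft(spec * np.conj(spec), nfft, axis=0)[:n_lags]
    return np.ascontiguousarray(acov.real) / n


@dataclass
class FluctuationTrace:
    """Mean-subtracted reflectance trace of one pixel."""

    delta_I: np.ndarray
    frame_interval: float            # s
    wavenumber: float                # um^-1

    def __post_init__(self):
        self.delta_I = np.asarray(self.delta_I, dtype=np.float64)
        if abs(self.delta_I.mean()) > 1e-9 * max(np.abs(self.delta_I).max(), 1e-300):
            raise ValueError("trace must be temporally mean-subtracted")

    @classmethod
    def from_cube(cls, cube: TemporalCube, y: int, x: int) -> "FluctuationTrace":
        trace = cube.intensities[:, y, x]
        return cls(delta_I=trace - trace.mean(),
                   frame_interval=cube.meta.frame_interval,
                   wavenumber=cube.meta.wavenumber)

    def acf(self, normalize: bool = False) -> "AutocorrelationResult":
        return temporal_acf(self.delta_I, self.frame_interval, normalize)


@dataclass
class AutocorrelationResult:
    """Per-lag autocovariance of a single fluctuation trace."""

    acf: np.ndarray
    lags: np.ndarray                  # seconds, starting at 0
    normalized: bool
    truncation_lag: int               # first non-positive lag index (n if none)
    t_c: float                        # correlation time, s (nan if undefined)

    @property
    def variance(self) -> float:
        return float(self.acf[0]) if not self.normalized else math.nan


def temporal_acf(trace: np.ndarray, frame_interval: float = 1.0,
                 normalize: bool = False) -> AutocorrelationResult:
    """Autocorrelation of one mean-subtracted pixel trace.

    The correlation time ``t_c`` is estimated from the log-slope between the
    first two nonzero lags of the normalized ACF (nan when the ACF is not
    positive there).
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1:
        raise ValueError("trace must be one-dimensional")
    if trace.shape[0] < 4:
        raise ValueError("trace must have at least 4 samples")
    delta = trace - trace.mean()
    acf = acf_cube(delta[:, None, None])[:, 0, 0]
    lags = np.arange(len(acf)) * frame_interval

    nonpos = np.flatnonzero(acf[1:] <= 0)
    truncation = int(nonpos[0]) + 1 if nonpos.size else len(acf)

    t_c = math.nan
    if acf[0] > 0 and truncation > 2:
        r1, r2 = acf[1] / acf[0], acf[2] / acf[0]
        if 0 < r2 < r1:
            t_c = -frame_interval / math.log(r2 / r1)
    out = acf / acf[0] if (normalize and acf[0] > 0) else acf
    return AutocorrelationResult(acf=out, lags=lags, normalized=normalize and acf[0] > 0,
                                 truncation_lag=truncation, t_c=t_c)


def background_acf(reference: ReferenceCube | TemporalCube,
                   n_lags: int | None = None) -> np.ndarray:
    """Spatial-mean ACF of an empty-field reference cube, shape (n_lags,)."""
    data = reference.intensities
    delta = data - data.mean(axis=0, keepdims=True)
    return acf_cube(delta, n_lags).mean(axis=(1, 2))


# ---------------------------------------------------------------------------
# Sigma_t^2 and fractional moving mass


@dataclass
class SigmaT2Map:
    """Reference-subtracted temporal variance per pixel."""

    sigma_t2: np.ndarray
    valid_mask: np.ndarray
    reference_level: float
    spatial_mean: float = math.nan   # unclamped mean(var) - reference level
    provenance: dict = field(default_factory=dict)


def compute_sigma_t2(cube: TemporalCube,
                     reference_cube: ReferenceCube | None = None) -> SigmaT2Map:
    """Per-pixel temporal variance of deltaI, minus the reference noise level.

    The spatial-mean Sigma_t^2 of the empty-field reference cube is
    subtracted from every pixel; negative results are clamped to zero and
    flagged invalid.
    """
    if reference_cube is not None and reference_cube.meta != cube.meta:
        raise CubeFormatError("reference cube metadata does not match sample cube")
    delta = cube.intensities - cube.intensities.mean(axis=0, keepdims=True)
    var = np.mean(delta**2, axis=0)
    ref_level = 0.0
    if reference_cube is not None:
        rdelta = reference_cube.intensities - reference_cube.intensities.mean(
            axis=0, keepdims=True)
        ref_level = float(np.mean(rdelta**2))
    out = var - ref_level
    valid = out >= 0
    return SigmaT2Map(sigma_t2=np.where(valid, out, 0.0), valid_mask=valid,
                      reference_level=ref_level,
                      spatial_mean=float(var.mean() - ref_level),
                      provenance={"reference_subtracted": reference_cube is not None})


def exposure_attenuation_factor(x):
    """Boxcar attenuation ``f(x) = 2 x^-2 (x - 1 + e^-x)`` of an exponential
    ACF integrated over an exposure window of ``x = exposure / t_c``
    correlation times.  ``f -> 1`` as ``x -> 0``."""
    x = np.asarray(x, dtype=np.float64)
    small = x < 1e-4  # series branch avoids cancellation in x - 1 + e^-x
    safe = np.where(small, 1.0, x)
    f = 2.0 / safe**2 * (safe - 1.0 + np.exp(-safe))
    return np.where(small, 1.0 - x / 3.0 + x**2 / 12.0, f)


def exposure_correction(sigma_t2, t_c: float, exposure_time: float):
    """Undo the variance attenuation caused by finite-exposure integration.

    Divides the measured variance by the closed-form boxcar factor for an
    exponential ACF with correlation time ``t_c``.
    """
    if t_c <= 0:
        raise ValueError("t_c must be positive")
    if exposure_time < 0:
        raise ValueError("exposure_time must be >= 0")
    f = exposure_attenuation_factor(exposure_time / t_c)
    return sigma_t2 / f


def fractional_moving_mass(sigma_t2_map, calibration_constant: float = 1.0):
    """m_f = calibration * Sigma_t^2 (normalized units by default).

    The absolute proportionality between interference variance and physical
    moving mass depends on instrument calibration; with the default constant
    of 1, m_f is reported in normalized units.
    """
    if calibration_constant < 0:
        raise ValueError("calibration constant must be non-negative")
    if isinstance(sigma_t2_map, SigmaT2Map):
        return calibration_constant * sigma_t2_map.sigma_t2
    return calibration_constant * np.asarray(sigma_t2_map)


# ---------------------------------------------------------------------------
# SNR filtering and diffusion estimation


def snr_filter(acf_per_pixel: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Valid-pixel mask: ACF(0) >= sqrt(2) x background ACF(0)."""
    bg0 = float(np.asarray(background).reshape(-1)[0])
    if bg0 <= 0:
        raise ValueError("background ACF(0) must be positive")
    return acf_per_pixel[0] >= SNR_THRESHOLD * bg0


def _resolve_background(cube: TemporalCube, reference) -> np.ndarray:
    if isinstance(reference, (ReferenceCube, TemporalCube)):
        return background_acf(reference)
    bg = np.asarray(reference, dtype=np.float64)
    if bg.ndim != 1:
        raise ValueError("background ACF must be 1-D (per lag)")
    return bg


@dataclass
class DMeanResult:
    """Whole-field diffusion estimate with diagnostics."""

    mean_D: float                    # um^2/s
    valid: bool
    n_valid_pixels: int
    fraction_retained: float
    mean_ln_acf: np.ndarray          # averaged ln of normalized ACF per lag
    lags: np.ndarray                 # seconds
    decay_rate: float                # 1/s (negative for decaying ACF)
    provenance: dict = field(default_factory=dict)

    @property
    def t_c(self) -> float:
        return -1.0 / self.decay_rate if self.decay_rate < 0 else math.nan


def _prepare_acfs(cube: TemporalCube, reference, n_lags: int):
    data = cube.intensities
    delta = data - data.mean(axis=0, keepdims=True)
    acfs = acf_cube(delta, n_lags)
    bg = _resolve_background(cube, reference)
    mask = snr_filter(acfs, bg)
    acfs = acfs - bg[:n_lags, None, None]
    return acfs, mask, bg


def estimate_D_mean(cube: TemporalCube, reference, meta: AcquisitionMeta | None = None,
                    slope_lags: tuple = (1, 2), max_lag: int = 32,
                    acf_average: str = "arithmetic") -> DMeanResult:
    """Whole-field diffusion coefficient from the mean log-ACF.

    Implements the eleven-step sequence (no spatial filter on this path):
    mean-subtract, per-pixel ACF, SNR filter against the background ACF,
    subtract the mean background ACF, normalize each ACF to one at lag zero,
    aggregate across valid pixels, truncate at the first non-positive value,
    take the two-point slope of the mean log-ACF at ``slope_lags``, and
    convert with ``D = -decay / (4 k^2)``.

    Aggregation across pixels (``acf_average``):

    * ``"arithmetic"`` (default): average the normalized ACFs, then take the
      log of the averaged curve.  Since the spatial mean of noisy per-pixel
      ACF estimates is an unbiased estimate of the ensemble ACF, the log of
      the mean is consistent; this is the robust estimate of the mean-ACF
      decay.
    * ``"geometric"``: average ln(ACF) across pixels (per-pixel truncation
      at the first non-positive lag).  With short traces the per-pixel ACF
      estimates fluctuate strongly at the slope lags and the log-average
      acquires a negative (Jensen) bias that steepens the apparent decay,
      overestimating D by tens of percent under typical phantom conditions;
      provided for comparison.

    ``reference`` may be an empty-field :class:`ReferenceCube` or a
    precomputed 1-D background ACF.
    """
    meta = meta or cube.meta
    l1, l2 = slope_lags
    if not (0 <= l1 < l2):
        raise ValueError("slope_lags must satisfy 0 <= first < second")
    n_lags = min(max(max_lag, l2 + 1), cube.n_frames)
    acfs, mask, bg = _prepare_acfs(cube, reference, n_lags)

    a0 = acfs[0]
    valid = mask & (a0 > 0)
    if not valid.any():
        raise EstimationError("no pixels pass the SNR filter")

    if acf_average == "arithmetic":
        norm = acfs[:, valid] / a0[valid]
        mean_curve = norm.mean(axis=1)
        # truncate the aggregated curve at its first non-positive value
        nonpos = np.flatnonzero(mean_curve[1:] <= 0)
        cutoff = int(nonpos[0]) + 1 if nonpos.size else n_lags
        mean_ln = np.full(n_lags, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_ln[:cutoff] = np.log(mean_curve[:cutoff])
    elif acf_average == "geometric":
        norm = np.where(valid[None], acfs / np.where(a0 > 0, a0, 1.0)[None], np.nan)
        # truncate at the first non-positive lag (per pixel), keeping lag 0
        nonpos = norm[1:] <= 0
        first_bad = np.where(nonpos.any(axis=0), nonpos.argmax(axis=0) + 1, n_lags)
        lag_idx = np.arange(n_lags)[:, None, None]
        usable = valid[None] & (lag_idx < first_bad[None])
        with np.errstate(invalid="ignore", divide="ignore"):
            ln = np.where(usable & (norm > 0),
                          np.log(np.where(norm > 0, norm, 1.0)), np.nan)
        counts = np.sum(~np.isnan(ln), axis=(1, 2))
        mean_ln = np.full(n_lags, np.nan)
        has = counts > 0
        mean_ln[has] = (np.nansum(np.where(np.isnan(ln), 0.0, ln), axis=(1, 2))[has]
                        / counts[has])
    else:
        raise ValueError(f"unknown acf_average {acf_average!r}")

    dt = meta.frame_interval
    if not (np.isfinite(mean_ln[l1]) and np.isfinite(mean_ln[l2])):
        raise EstimationError("mean log-ACF undefined at the slope lags")
    decay = (mean_ln[l2] - mean_ln[l1]) / ((l2 - l1) * dt)
    k = meta.wavenumber
    d = -decay / (4.0 * k**2)
    return DMeanResult(
        mean_D=d, valid=d > 0, n_valid_pixels=int(valid.sum()),
        fraction_retained=float(valid.mean()),
        mean_ln_acf=mean_ln, lags=np.arange(n_lags) * dt, decay_rate=decay,
        provenance={
            "k_um_inv": k, "k_convention": "medium (k = 2*pi*n/lambda)",
            "slope_lags": (l1, l2), "snr_threshold": SNR_THRESHOLD,
            "acf_average": acf_average, "spatial_filter_sigma_px": 0.0,
        })


@dataclass
class DMapResult:
    """Per-pixel diffusion map."""

    D: np.ndarray                    # um^2/s, nan where invalid
    valid_mask: np.ndarray
    provenance: dict = field(default_factory=dict)


def estimate_D_map(cube: TemporalCube, reference, meta: AcquisitionMeta | None = None,
                   gaussian_sigma_px: float = 2.0,
                   slope_lags: tuple = (1, 2)) -> DMapResult:
    """Per-pixel diffusion map with per-lag spatial smoothing of the ACF.

    Identical to :func:`estimate_D_mean` through background subtraction,
    then each lag plane of the ACF stack is smoothed with a spatial Gaussian
    (sigma ``gaussian_sigma_px``; 0 disables smoothing and reproduces the
    unsmoothed per-pixel path exactly) before per-pixel normalization,
    truncation and the two-point log slope.
    """
    meta = meta or cube.meta
    l1, l2 = slope_lags
    n_lags = l2 + 1
    acfs, mask, bg = _prepare_acfs(cube, reference, n_lags)
    if gaussian_sigma_px > 0:
        for m in range(n_lags):
            acfs[m] = ndimage.gaussian_filter(acfs[m], gaussian_sigma_px)

    a0 = acfs[0]
    valid = mask & (a0 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = acfs / np.where(a0 > 0, a0, np.nan)[None]
    # pixel unusable if the ACF goes non-positive at or before the slope lags
    needed = norm[1:l2 + 1]
    valid = valid & np.all(needed > 0, axis=0)
    dt = meta.frame_interval
    with np.errstate(invalid="ignore", divide="ignore"):
        if l1 == 0:
            decay = np.log(norm[l2]) / (l2 * dt)
        else:
            decay = (np.log(norm[l2]) - np.log(norm[l1])) / ((l2 - l1) * dt)
    k = meta.wavenumber
    d = -decay / (4.0 * k**2)
    valid = valid & np.isfinite(d) & (d > 0)
    return DMapResult(
        D=np.where(valid, d, np.nan), valid_mask=valid,
        provenance={
            "k_um_inv": k, "k_convention": "medium (k = 2*pi*n/lambda)",
            "slope_lags": (l1, l2), "snr_threshold": SNR_THRESHOLD,
            "spatial_filter_sigma_px": gaussian_sigma_px,
        })


# ---------------------------------------------------------------------------
# assembled maps and sensitivity range


@dataclass
class DynamicsMaps:
    """Per-pixel dynamics outputs of one temporal cube."""

    sigma_t2: np.ndarray
    m_f: np.ndarray
    D: np.ndarray
    valid_mask: np.ndarray
    mean_D: float
    provenance: dict = field(default_factory=dict)


def compute_dynamics_maps(cube: TemporalCube, reference_cube: ReferenceCube | None = None,
                          gaussian_sigma_px: float = 2.0,
                          calibration_constant: float = 1.0,
                          slope_lags: tuple = (1, 2)) -> DynamicsMaps:
    """Sigma_t^2, m_f and D maps plus the whole-field mean D for one cube."""
    s = compute_sigma_t2(cube, reference_cube)
    mf = fractional_moving_mass(s, calibration_constant)
    ref = reference_cube if reference_cube is not None else background_acf(cube)
    try:
        dmean = estimate_D_mean(cube, ref, slope_lags=slope_lags)
        mean_d = dmean.mean_D
    except EstimationError:
        mean_d = math.nan
    dmap = estimate_D_map(cube, ref, gaussian_sigma_px=gaussian_sigma_px,
                          slope_lags=slope_lags)
    prov = dict(dmap.provenance)
    prov["calibration_constant"] = calibration_constant
    prov["reference_subtracted"] = reference_cube is not None
    return DynamicsMaps(sigma_t2=s.sigma_t2, m_f=mf, D=dmap.D,
                        valid_mask=s.valid_mask & dmap.valid_mask,
                        mean_D=mean_d, provenance=prov)


def sensitivity_range(exposure_time: float, acquisition_time: float, k: float,
                      convention: str = "t_c_bracket") -> tuple:
    """Accessible diffusion-coefficient window (D_min, D_max), um^2/s.

    Under the documented bracketing convention the correlation time must be
    resolvable within the acquisition yet not fully averaged within one
    exposure, ``t_c in [exposure_time, acquisition_time]``, giving
    ``D_max = 1/(4 k^2 T_exp)`` and ``D_min = 1/(4 k^2 DeltaT)``.
    """
    if exposure_time >= acquisition_time:
        raise ValueError("exposure must be shorter than the acquisition")
    d_max = 1.0 / (4.0 * k**2 * exposure_time)
    d_min = 1.0 / (4.0 * k**2 * acquisition_time)
    return d_min, d_max
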