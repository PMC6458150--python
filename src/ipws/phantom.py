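"""Physics-based nanosphere-phantom simulator.

Generates synthetic temporal and spectral image cubes from first principles:
a strong reference reflection at the substrate-medium interface interferes
with the weak field backscattered by nanoscale spheres suspended in a
viscous medium.  The forward model is scalar and first-Born (single
scattering, Rayleigh regime, sphere radii 25-100 nm << lambda):

    E(p, t) = sqrt(R_ref) + sum_j  a_j * W(p - x_j(t)) * exp(i(2 k z_j(t) + phi_j))
    I(p, t) = |E(p, t)|^2

with ``W`` a Gaussian lateral point-spread weight (sigma ~ 0.21 lambda/NA),
``k`` the wavenumber in the medium, and ``phi_j`` a fixed random scattering
phase per sphere.  Backscattering doubles the phase rate (2 k z), so axial
Brownian motion decorrelates the interference signal at rate ``4 k^2 D`` --
the relation the temporal-dynamics estimator inverts.  The detector
integrates *intensity* over the finite exposure window, which the renderer
reproduces by averaging substep intensities; shot noise, read noise and a
slowly drifting LED are applied on top.

Lateral coordinates are periodic over the field of view and the lateral
point-spread convolution is circular, so the scatterer density is exactly
stationary over arbitrarily long acquisitions.

The simulator's own parameters feed an analytic expression for the expected
temporal variance (:func:`analytic_sigma_t2`), which serves as ground truth
for end-to-end validation of the measurement pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import fft as sp_fft

from . import constants
from .cubes import AcquisitionMeta, CubeMetadataError, ReferenceCube, SpectralCube, TemporalCube

__all__ = [
    "ScattererEnsemble",
    "NoiseModel",
    "Trajectories",
    "GroundTruthManifest",
    "PhantomCondition",
    "PhantomRealization",
    "stokes_einstein",
    "simulate_brownian",
    "render_interference",
    "render_spectral",
    "render_reference",
    "analytic_sigma_t2",
    "make_ensemble",
    "make_phantom_suite",
    "simulate_paroxysm_cube",
    "psf_sigma_um",
    "phantom_meta",
]


def stokes_einstein(radius_nm: float, viscosity_pa_s: float,
                    temperature_k: float = constants.DEFAULT_TEMPERATURE_K) -> float:
    """Diffusion coefficient of a sphere, um^2/s.

    ``D = k_B T / (6 pi eta r)`` for a sphere of radius ``r`` in a fluid of
    viscosity ``eta``.
    """
    if radius_nm <= 0 or viscosity_pa_s <= 0 or temperature_k <= 0:
        raise ValueError("radius, viscosity and temperature must all be positive")
    d_m2_s = constants.BOLTZMANN_J_PER_K * temperature_k / (
        6.0 * math.pi * viscosity_pa_s * radius_nm * 1e-9
    )
    return d_m2_s * 1e12  # m^2/s -> um^2/s


def psf_sigma_um(wavelength_nm: float, numerical_aperture: float) -> float:
    """Gaussian lateral weight sigma, um (~0.21 lambda / NA).

    The interference term measures the overlap of the scattered field with
    the reference beam, so the lateral sensitivity kernel is set by the
    illumination/reference mode (NA 0.55), not by the collection PSF: a
    sphere contributes for as long as it stays inside the reference beam
    waist.  Using the collection NA here would add a spurious lateral-
    transit decay of order 1/(4 k^2 sigma^2) ~ 10% of the axial phase
    decorrelation rate, inconsistent with the exp(-4 k^2 D tau) law the
    simulator must reproduce."""
    return 0.21 * wavelength_nm * 1e-3 / numerical_aperture


@dataclass
class ScattererEnsemble:
    """Ground-truth description of the simulated nanosphere suspension.

    ``positions`` are (x, y, z) in um with z measured from the reference
    interface into the medium; lateral coordinates live on a periodic domain
    of size ``domain_um`` = (Lx, Ly).  ``scattering_amplitude`` is the
    dimensionless field amplitude of one sphere relative to unit incident
    field, proportional to sphere volume times the refractive-index contrast
    (Rayleigh scaling a ~ r^3 (n_s^2 - n_m^2)).
    """

    positions: np.ndarray            # (N, 3) um
    radius_nm: float
    scattering_amplitude: float
    sphere_refractive_index: float
    medium_refractive_index: float
    medium_viscosity: float          # Pa*s
    temperature_k: float
    volume_fraction: float
    domain_um: tuple                 # (Lx, Ly) periodic lateral extent
    depth_um: float                  # axial placement window
    mobile: np.ndarray = None        # (N,) bool
    phases: np.ndarray = None        # (N,) rad, fixed per run

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        n = len(self.positions)
        if self.mobile is None:
            self.mobile = np.ones(n, dtype=bool)
        self.mobile = np.asarray(self.mobile, dtype=bool)
        if self.phases is None:
            self.phases = np.zeros(n)
        self.phases = np.asarray(self.phases, dtype=np.float64)
        if not (0 < self.volume_fraction <= 0.05):
            raise ValueError("volume_fraction must lie in (0, 0.05]")
        if self.radius_nm <= 0 or self.medium_viscosity <= 0:
            raise ValueError("radius and viscosity must be positive")

    @property
    def n_scatterers(self) -> int:
        return len(self.positions)

    @property
    def true_D(self) -> float:
        """Stokes-Einstein diffusion coefficient of a mobile sphere, um^2/s."""
        return stokes_einstein(self.radius_nm, self.medium_viscosity, self.temperature_k)

    @property
    def number_density(self) -> float:
        """Spheres per um^3 implied by the volume fraction."""
        v_sphere = 4.0 / 3.0 * math.pi * (self.radius_nm * 1e-3) ** 3
        return self.volume_fraction / v_sphere


@dataclass
class NoiseModel:
    """Detection-noise model applied to rendered intensity frames.

    ``photon_budget`` is the expected photon count per pixel per frame at the
    reference reflectance level; it sets the shot-noise floor.  LED drift is
    a multiplicative AR(1) process common to all pixels with stationary
    standard deviation ``led_drift_amplitude`` and correlation time
    ``led_drift_tau`` seconds.
    """

    photon_budget: float = 4e5
    read_noise_sd: float = 2.0       # counts (photon-equivalent)
    led_drift_amplitude: float = 2e-3
    led_drift_tau: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive")
        if self.led_drift_amplitude < 0:
            raise ValueError("led_drift_amplitude must be >= 0")

    def to_dict(self) -> dict:
        return {
            "photon_budget": self.photon_budget,
            "read_noise_sd": self.read_noise_sd,
            "led_drift_amplitude": self.led_drift_amplitude,
            "led_drift_tau": self.led_drift_tau,
        }

    def drift(self, n_frames: int, frame_interval: float, rng: np.random.Generator) -> np.ndarray:
        """Multiplicative LED intensity factor per frame."""
        if self.led_drift_amplitude == 0:
            return np.ones(n_frames)
        rho = math.exp(-frame_interval / self.led_drift_tau)
        eps = np.empty(n_frames)
        eps[0] = rng.normal(0.0, self.led_drift_amplitude)
        innov = rng.normal(0.0, self.led_drift_amplitude * math.sqrt(1 - rho**2), n_frames)
        for i in range(1, n_frames):
            eps[i] = rho * eps[i - 1] + innov[i]
        return 1.0 + eps

    def apply(self, frames: np.ndarray, reference_reflectance: float,
              frame_interval: float, rng: np.random.Generator) -> np.ndarray:
        """Shot noise + read noise + LED drift, in reflectance units."""
        scale = self.photon_budget / reference_reflectance  # counts per unit reflectance
        d = self.drift(frames.shape[0], frame_interval, rng)[:, None, None]
        lam = np.clip(frames * d * scale, 0.0, None)
        counts = rng.poisson(lam).astype(np.float64)
        if self.read_noise_sd > 0:
            counts += rng.normal(0.0, self.read_noise_sd, size=counts.shape)
        return counts / scale


@dataclass
class Trajectories:
    """Scatterer positions sampled at every exposure substep.

    ``times`` is the flat (n_frames * substeps,) array of sample times and
    ``positions`` has shape (n_scatterers, n_samples, 3) in um.
    """

    times: np.ndarray
    positions: np.ndarray
    n_frames: int
    substeps: int


def _sample_times(n_frames: int, frame_interval: float, exposure_time: float,
                  substeps: int) -> np.ndarray:
    offsets = (np.arange(substeps) + 0.5) / substeps * exposure_time
    starts = np.arange(n_frames) * frame_interval
    return (starts[:, None] + offsets[None, :]).ravel()


def simulate_brownian(ensemble: ScattererEnsemble, frame_interval: float,
                      n_frames: int, substeps: int = 10, seed=None,
                      exposure_time: float | None = None) -> Trajectories:
    """Free 3-D Brownian motion of the mobile spheres.

    Each mobile sphere takes independent Gaussian steps with per-axis
    variance ``2 D dt`` between consecutive sample times (``substeps``
    samples spread over each exposure window); immobile spheres stay put.
    Deterministic under a fixed seed.
    """
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    d_um2_s = ensemble.true_D
    if not np.isfinite(d_um2_s):
        raise ValueError("non-finite diffusion coefficient")
    if exposure_time is None:
        exposure_time = frame_interval
    times = _sample_times(n_frames, frame_interval, exposure_time, substeps)
    rng = np.random.default_rng(seed)
    n = ensemble.n_scatterers
    nt = len(times)
    dts = np.diff(times)
    step_sd = np.sqrt(2.0 * d_um2_s * dts)  # (nt-1,)
    pos = np.empty((n, nt, 3), dtype=np.float32)
    pos[:, 0, :] = ensemble.positions
    steps = rng.standard_normal((n, nt - 1, 3)).astype(np.float32)
    steps *= step_sd[None, :, None].astype(np.float32)
    steps[~ensemble.mobile] = 0.0
    np.cumsum(steps, axis=1, out=steps)
    pos[:, 1:, :] = ensemble.positions[:, None, :].astype(np.float32) + steps
    return Trajectories(times=times, positions=pos, n_frames=n_frames, substeps=substeps)


def _gaussian_otf(shape, sigma_px: float):
    ny, nx = shape
    dy = np.minimum(np.arange(ny), ny - np.arange(ny)).astype(np.float64)
    dx = np.minimum(np.arange(nx), nx - np.arange(nx)).astype(np.float64)
    kernel = np.exp(-(dy[:, None] ** 2 + dx[None, :] ** 2) / (2.0 * sigma_px**2))
    return sp_fft.fft2(kernel)


def _deposit_bilinear(xs, ys, amps, shape, n_slices, slice_idx):
    """Scatter complex amplitudes onto (n_slices, ny, nx) with periodic wrap."""
    ny, nx = shape
    x0 = np.floor(xs).astype(np.int64)
    y0 = np.floor(ys).astype(np.int64)
    fx = xs - x0
    fy = ys - y0
    grid = np.zeros(n_slices * ny * nx, dtype=np.complex128)
    base = slice_idx * (ny * nx)
    for dy_, dx_, w in (
        (0, 0, (1 - fy) * (1 - fx)),
        (0, 1, (1 - fy) * fx),
        (1, 0, fy * (1 - fx)),
        (1, 1, fy * fx),
    ):
        iy = (y0 + dy_) % ny
        ix = (x0 + dx_) % nx
        idx = base + iy * nx + ix
        wa = w * amps
        grid += np.bincount(idx, weights=wa.real, minlength=grid.size)
        grid += 1j * np.bincount(idx, weights=wa.imag, minlength=grid.size)
    return grid.reshape(n_slices, ny, nx)


def render_interference(trajectories: Trajectories, ensemble: ScattererEnsemble,
                        meta: AcquisitionMeta, shape,
                        reference_reflectance: float | None = None,
                        noise_model: NoiseModel | None = None,
                        rng=None, chunk_frames: int | None = None) -> TemporalCube:
    """Render a temporal interference cube from scatterer trajectories.

    Per substep the complex scattered field is deposited bilinearly onto the
    pixel grid, convolved (circularly) with the Gaussian lateral PSF, summed
    with the reference field sqrt(R_ref), and squared to intensity; substep
    intensities are averaged within each exposure window (the detector
    integrates intensity, not field).  Noise per ``noise_model``.
    """
    if meta.exposure_time > meta.frame_interval * (1 + 1e-12):
        raise CubeMetadataError("exposure longer than frame interval")
    ny, nx = shape
    if reference_reflectance is None:
        reference_reflectance = constants.fresnel_reflectance(
            constants.SAPPHIRE_RI, ensemble.medium_refractive_index)
    k = meta.wavenumber
    sigma_px = psf_sigma_um(meta.wavelength, meta.illumination_na) / meta.pixel_size
    otf = _gaussian_otf((ny, nx), sigma_px)
    sqrt_r = math.sqrt(reference_reflectance)

    n_frames, substeps = trajectories.n_frames, trajectories.substeps
    pos = trajectories.positions  # (N, T, 3)
    a = ensemble.scattering_amplitude
    phases = ensemble.phases
    inv_px = 1.0 / meta.pixel_size

    if chunk_frames is None:
        # bound transient memory: ~1e7 scatterer-slice entries per chunk
        chunk_frames = int(np.clip(1e7 // max(pos.shape[0] * substeps, 1), 1, 64))
    frames = np.empty((n_frames, ny, nx), dtype=np.float64)
    for f0 in range(0, n_frames, chunk_frames):
        f1 = min(f0 + chunk_frames, n_frames)
        s0, s1 = f0 * substeps, f1 * substeps
        nsl = s1 - s0
        p = pos[:, s0:s1, :].astype(np.float64)            # (N, nsl, 3)
        amps = a * np.exp(1j * (2.0 * k * p[:, :, 2] + phases[:, None]))
        slice_idx = np.broadcast_to(np.arange(nsl)[None, :], amps.shape)
        grid = _deposit_bilinear(
            (p[:, :, 0] * inv_px).ravel(), (p[:, :, 1] * inv_px).ravel(),
            amps.ravel(), (ny, nx), nsl, slice_idx.ravel())
        scat = sp_fft.ifft2(sp_fft.fft2(grid, axes=(-2, -1)) * otf, axes=(-2, -1))
        intensity = np.abs(sqrt_r + scat) ** 2
        frames[f0:f1] = intensity.reshape(f1 - f0, substeps, ny, nx).mean(axis=1)

    out_rng = rng if rng is not None else np.random.default_rng(
        noise_model.seed if noise_model is not None else None)
    if noise_model is not None:
        frames = noise_model.apply(frames, reference_reflectance,
                                   meta.frame_interval, out_rng)
    prov = {
        "simulated": True,
        "reference_reflectance": reference_reflectance,
        "k_convention": "medium (k = 2*pi*n/lambda)",
        "true_D_um2_s": ensemble.true_D if ensemble.mobile.any() else 0.0,
        "noise": noise_model.to_dict() if noise_model is not None else None,
    }
    return TemporalCube(intensities=frames, meta=meta, provenance=prov)


def render_spectral(positions: np.ndarray, ensemble: ScattererEnsemble,
                    meta: AcquisitionMeta, shape,
                    reference_reflectance: float | None = None,
                    noise_model: NoiseModel | None = None,
                    rng=None) -> SpectralCube:
    """Render a spectral cube from a static snapshot of scatterer positions.

    The same field model is evaluated per wavelength (k varies with lambda),
    so a sphere at depth z imprints a spectral oscillation cos(2 k z + phi)
    whose frequency grows with depth.
    """
    if len(meta.wavelengths) < 3:
        raise CubeMetadataError("spectral rendering requires >= 3 wavelengths")
    ny, nx = shape
    if reference_reflectance is None:
        reference_reflectance = constants.fresnel_reflectance(
            constants.SAPPHIRE_RI, ensemble.medium_refractive_index)
    sqrt_r = math.sqrt(reference_reflectance)
    pos = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    ks = meta.wavenumbers  # (W,)
    w = len(ks)
    sigma_px = psf_sigma_um(float(np.mean(meta.wavelengths)),
                            meta.illumination_na) / meta.pixel_size
    otf = _gaussian_otf((ny, nx), sigma_px)
    a = ensemble.scattering_amplitude
    inv_px = 1.0 / meta.pixel_size

    amps = a * np.exp(1j * (2.0 * ks[None, :] * pos[:, 2:3] + ensemble.phases[:, None]))
    slice_idx = np.broadcast_to(np.arange(w)[None, :], amps.shape)
    xs = np.broadcast_to((pos[:, 0] * inv_px)[:, None], amps.shape)
    ys = np.broadcast_to((pos[:, 1] * inv_px)[:, None], amps.shape)
    grid = _deposit_bilinear(xs.ravel(), ys.ravel(), amps.ravel(), (ny, nx),
                             w, slice_idx.ravel())
    scat = sp_fft.ifft2(sp_fft.fft2(grid, axes=(-2, -1)) * otf, axes=(-2, -1))
    frames = np.abs(sqrt_r + scat) ** 2

    out_rng = rng if rng is not None else np.random.default_rng(
        noise_model.seed if noise_model is not None else None)
    if noise_model is not None:
        frames = noise_model.apply(frames, reference_reflectance,
                                   meta.frame_interval, out_rng)
    prov = {"simulated": True, "reference_reflectance": reference_reflectance}
    return SpectralCube(intensities=frames, meta=meta, provenance=prov)


def render_reference(meta: AcquisitionMeta, shape, reference_reflectance: float,
                     noise_model: NoiseModel, rng) -> ReferenceCube:
    """Empty-field reference cube: reference reflectance plus noise only."""
    ny, nx = shape
    frames = np.full((meta.n_frames, ny, nx), reference_reflectance)
    frames = noise_model.apply(frames, reference_reflectance, meta.frame_interval, rng)
    return ReferenceCube(intensities=frames, meta=meta,
                         provenance={"simulated": True, "is_reference": True})


def mean_kernel_power(shape, sigma_px: float, n_offsets: int = 5) -> float:
    """Mean over subpixel positions of sum_p W(p - x)^2 for the discrete PSF.

    The discrete response to a unit-amplitude scatterer is the bilinear
    deposition footprint convolved with the Gaussian kernel; this returns
    the expected sum of squared pixel weights, which the analytic variance
    expression needs.
    """
    ny, nx = shape
    otf = _gaussian_otf((ny, nx), sigma_px)
    offs = (np.arange(n_offsets) + 0.5) / n_offsets
    total = 0.0
    for fy in offs:
        for fx in offs:
            amps = np.array([(1 - fy) * (1 - fx), (1 - fy) * fx,
                             fy * (1 - fx), fy * fx], dtype=np.complex128)
            grid = np.zeros((1, ny, nx), dtype=np.complex128)
            grid[0, 0, 0], grid[0, 0, 1], grid[0, 1, 0], grid[0, 1, 1] = amps
            resp = sp_fft.ifft2(sp_fft.fft2(grid, axes=(-2, -1)) * otf, axes=(-2, -1))
            total += float(np.sum(np.abs(resp) ** 2))
    return total / n_offsets**2


def analytic_sigma_t2(ensemble: ScattererEnsemble, meta: AcquisitionMeta, shape,
                      reference_reflectance: float | None = None) -> float:
    """Expected spatial-mean temporal variance of the interference signal.

    For mobile spheres whose phase 2 k z + phi randomizes over the
    acquisition, each sphere contributes temporal variance
    ``2 R_ref a^2 W(p - x_j)^2`` at pixel p (heterodyne term only);
    averaging over uniform sphere positions gives

        Sigma_t^2 = 2 R_ref a^2 * N * <sum_p W^2> / n_pixels

    evaluated with the same discrete kernel the renderer uses.  This is the
    *unattenuated* value; finite exposure reduces the measured variance by
    the boxcar factor handled in :func:`ipws.dynamics.exposure_correction`.
    """
    ny, nx = shape
    if reference_reflectance is None:
        reference_reflectance = constants.fresnel_reflectance(
            constants.SAPPHIRE_RI, ensemble.medium_refractive_index)
    sigma_px = psf_sigma_um(meta.wavelength, meta.illumination_na) / meta.pixel_size
    n_mobile = int(ensemble.mobile.sum())
    w2 = mean_kernel_power((ny, nx), sigma_px)
    return (2.0 * reference_reflectance * ensemble.scattering_amplitude**2
            * n_mobile * w2 / (ny * nx))


# ---------------------------------------------------------------------------
# phantom suite


def phantom_meta(wavelength_nm: float = 550.0, exposure_time: float = 0.032,
                 frame_interval: float = 0.032, n_frames: int = 201,
                 pixel_size: float = 0.1, medium_refractive_index: float = 1.46,
                 **kw) -> AcquisitionMeta:
    """Acquisition metadata defaulting to the nanosphere-phantom settings
    (32 ms exposure, 201 frames = 6.432 s acquisition, 550 nm)."""
    return AcquisitionMeta(
        wavelengths=(wavelength_nm,), exposure_time=exposure_time,
        frame_interval=frame_interval, n_frames=n_frames,
        pixel_size=pixel_size, medium_refractive_index=medium_refractive_index,
        **kw)


#: dimensionless prefactor of the Rayleigh scattering amplitude
#: a = AMPLITUDE_SCALE * (r / 100 nm)^3 * (n_s^2 - n_m^2); sets the overall
#: heterodyne signal level (a << sqrt(R_ref) for all phantom radii)
DEFAULT_AMPLITUDE_SCALE = 0.07


def make_ensemble(radius_nm: float, volume_fraction: float, shape, meta: AcquisitionMeta,
                  depth_um: float = 4.0,
                  medium_viscosity: float | None = None,
                  sphere_refractive_index: float = constants.POLYSTYRENE_RI,
                  temperature_k: float = constants.DEFAULT_TEMPERATURE_K,
                  amplitude_scale: float = DEFAULT_AMPLITUDE_SCALE,
                  mobile: bool = True, rng=None) -> ScattererEnsemble:
    """Draw a random sphere ensemble filling the field of view.

    The sphere count is Poisson with mean ``number_density * volume``;
    positions are uniform over the periodic lateral domain and the axial
    window ``[0, depth_um]``; scattering phases are uniform on [0, 2 pi).
    """
    rng = np.random.default_rng(rng)
    ny, nx = shape
    lx, ly = nx * meta.pixel_size, ny * meta.pixel_size
    n_m = meta.medium_refractive_index
    if medium_viscosity is None:
        medium_viscosity = constants.GLYCEROL_VISCOSITY_PA_S[90]
    v_sphere = 4.0 / 3.0 * math.pi * (radius_nm * 1e-3) ** 3
    density = volume_fraction / v_sphere
    n = max(1, int(rng.poisson(density * lx * ly * depth_um)))
    positions = np.column_stack([
        rng.uniform(0, lx, n), rng.uniform(0, ly, n), rng.uniform(0, depth_um, n)])
    amplitude = amplitude_scale * (radius_nm / 100.0) ** 3 * (
        sphere_refractive_index**2 - n_m**2)
    return ScattererEnsemble(
        positions=positions, radius_nm=radius_nm, scattering_amplitude=amplitude,
        sphere_refractive_index=sphere_refractive_index, medium_refractive_index=n_m,
        medium_viscosity=medium_viscosity, temperature_k=temperature_k,
        volume_fraction=volume_fraction, domain_um=(lx, ly), depth_um=depth_um,
        mobile=np.full(n, bool(mobile)), phases=rng.uniform(0, 2 * math.pi, n))


@dataclass
class PhantomCondition:
    """One simulated phantom condition (sphere size x concentration x medium)."""

    radius_nm: float
    volume_fraction: float = 0.001
    glycerol_pct: int = 90
    mobile: bool = True
    depth_um: float = 4.0
    amplitude_scale: float = DEFAULT_AMPLITUDE_SCALE

    @property
    def viscosity(self) -> float:
        return constants.GLYCEROL_VISCOSITY_PA_S[self.glycerol_pct]

    @property
    def medium_refractive_index(self) -> float:
        return constants.GLYCEROL_REFRACTIVE_INDEX[self.glycerol_pct]

    @property
    def true_D(self) -> float:
        return stokes_einstein(self.radius_nm, self.viscosity) if self.mobile else 0.0


@dataclass
class GroundTruthManifest:
    """Traceability record for one emitted phantom cube."""

    condition: PhantomCondition
    true_D: float
    sigma_t2_analytic: float
    n_scatterers: int
    scattering_amplitude: float
    seed: int
    k_um_inv: float
    reference_reflectance: float
    noise: dict
    meta: dict

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["condition"] = dict(self.condition.__dict__)
        return d


@dataclass
class PhantomRealization:
    """One simulated cube with its empty-field reference and ground truth."""

    cube: TemporalCube
    reference: ReferenceCube
    ensemble: ScattererEnsemble
    manifest: GroundTruthManifest


def _auto_substeps(exposure_time: float, true_D: float, k: float,
                   minimum: int = 10, maximum: int = 20) -> int:
    """Enough substeps that the correlation time is resolved within the
    exposure window (>= 4 samples per t_c), floor 10."""
    if true_D <= 0:
        return minimum
    t_c = 1.0 / (4.0 * k**2 * true_D)
    return int(np.clip(math.ceil(4.0 * exposure_time / t_c), minimum, maximum))


def make_phantom_suite(conditions: Sequence[PhantomCondition], seed: int,
                       shape=(64, 64), meta: AcquisitionMeta | None = None,
                       noise_model: NoiseModel | None = None,
                       substeps: int | None = None) -> list:
    """Simulate one cube + empty-field reference per condition.

    Returns a list of :class:`PhantomRealization`.  Fixed ``seed`` gives a
    bit-identical suite; per-condition streams are spawned from it so
    conditions are independent.
    """
    if noise_model is None:
        noise_model = NoiseModel()
    realizations = []
    child_seeds = np.random.SeedSequence(seed).spawn(len(conditions))
    for cond, ss in zip(conditions, child_seeds):
        rng = np.random.default_rng(ss)
        m = (meta or phantom_meta()).replace(
            medium_refractive_index=cond.medium_refractive_index)
        ens = make_ensemble(cond.radius_nm, cond.volume_fraction, shape, m,
                            depth_um=cond.depth_um, medium_viscosity=cond.viscosity,
                            amplitude_scale=cond.amplitude_scale,
                            mobile=cond.mobile, rng=rng)
        nsub = substeps if substeps is not None else _auto_substeps(
            m.exposure_time, ens.true_D if cond.mobile else 0.0, m.wavenumber)
        traj = simulate_brownian(ens, m.frame_interval, m.n_frames,
                                 substeps=nsub, seed=rng,
                                 exposure_time=m.exposure_time)
        r_ref = constants.fresnel_reflectance(constants.SAPPHIRE_RI,
                                              m.medium_refractive_index)
        cube = render_interference(traj, ens, m, shape, r_ref, noise_model, rng)
        reference = render_reference(m, shape, r_ref, noise_model, rng)
        manifest = GroundTruthManifest(
            condition=cond, true_D=cond.true_D,
            sigma_t2_analytic=analytic_sigma_t2(ens, m, shape, r_ref),
            n_scatterers=ens.n_scatterers,
            scattering_amplitude=ens.scattering_amplitude,
            seed=int(ss.entropy) if isinstance(ss.entropy, int) else seed,
            k_um_inv=m.wavenumber, reference_reflectance=r_ref,
            noise=noise_model.to_dict(), meta=m.to_dict())
        realizations.append(PhantomRealization(cube=cube, reference=reference,
                                               ensemble=ens, manifest=manifest))
    return realizations


def simulate_paroxysm_cube(n_frames: int, onset_map: np.ndarray,
                           amplitude_map: np.ndarray,
                           meta: AcquisitionMeta | None = None,
                           baseline: float = 1.0, noise_sd: float = 1e-3,
                           mean_shift_map: np.ndarray | None = None,
                           rng=None) -> TemporalCube:
    """Synthetic burst-of-motion cube for changepoint benchmarking.

    Each pixel's trace is quiescent Gaussian noise (sd ``noise_sd``) before
    its onset frame and gains a step in fluctuation amplitude (sd multiplied
    by ``amplitude_map``) -- and optionally in mean -- from the onset frame
    onward.  Pixels with a negative onset never fire.  Ground truth is
    stored in the cube provenance.
    """
    onset_map = np.asarray(onset_map)
    amplitude_map = np.asarray(amplitude_map, dtype=np.float64)
    if np.any(onset_map >= n_frames):
        raise ValueError("onset frame beyond the acquisition")
    rng = np.random.default_rng(rng)
    ny, nx = onset_map.shape
    if meta is None:
        meta = phantom_meta(exposure_time=0.035, frame_interval=0.035,
                            n_frames=n_frames)
    t = np.arange(n_frames)[:, None, None]
    fired = (onset_map[None, :, :] >= 0) & (t >= onset_map[None, :, :])
    sd = np.where(fired, amplitude_map[None, :, :] * noise_sd, noise_sd)
    traces = baseline + rng.standard_normal((n_frames, ny, nx)) * sd
    if mean_shift_map is not None:
        traces += np.where(fired, np.asarray(mean_shift_map)[None, :, :], 0.0)
    prov = {"simulated": True, "paroxysm_truth": {
        "onset_map": onset_map.tolist(), "noise_sd": noise_sd}}
    return TemporalCube(intensities=traces, meta=meta.replace(n_frames=n_frames),
                        provenance=prov)
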