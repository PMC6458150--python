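import numpy as np
import pytest

from ipws.cubes import AcquisitionMeta, TemporalCube
from ipws.phantom import NoiseModel, make_ensemble, phantom_meta


@pytest.fixture
def temporal_meta():
    return AcquisitionMeta(
        wavelengths=(550.0,), exposure_time=0.032, frame_interval=0.032,
        n_frames=64, pixel_size=0.1, medium_refractive_index=1.46)


@pytest.fixture
def spectral_meta():
    wl = tuple(np.linspace(500, 700, 101))
    return AcquisitionMeta(
        wavelengths=wl, exposure_time=0.035, frame_interval=0.035,
        n_frames=101, pixel_size=0.1, medium_refractive_index=1.46)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cube(temporal_meta, rng):
    data = 0.01 + 1e-4 * rng.standard_normal((64, 8, 8))
    return TemporalCube(intensities=data, meta=temporal_meta)


def make_ar1_cube(t_c, n_frames, shape, frame_interval=0.032, scale=1e-4,
                  baseline=0.01, seed=0):
    """Stationary Gaussian pixel ensemble with exact exponential ACF
    exp(-tau/t_c); the independent reference process for ACF estimators."""
    rng = np.random.default_rng(seed)
    rho = np.exp(-frame_interval / t_c)
    ny, nx = shape
    x = np.empty((n_frames, ny * nx))
    x[0] = rng.standard_normal(ny * nx)
    innov = rng.standard_normal((n_frames - 1, ny * nx)) * np.sqrt(1 - rho**2)
    for i in range(1, n_frames):
        x[i] = rho * x[i - 1] + innov[i - 1]
    meta = AcquisitionMeta(
        wavelengths=(550.0,), exposure_time=frame_interval,
        frame_interval=frame_interval, n_frames=n_frames, pixel_size=0.1,
        medium_refractive_index=1.46)
    return TemporalCube(intensities=baseline + scale * x.reshape(n_frames, ny, nx),
                        meta=meta)
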