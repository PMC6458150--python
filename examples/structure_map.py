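"""Compute a Sigma_s structure map from a simulated spectral cube.

A static snapshot of the sphere suspension is imaged across 500-700 nm;
each sphere imprints a depth-dependent spectral oscillation on the
interference with the substrate reflection, and Sigma_s (the per-pixel
standard deviation of the detrended spectrum) maps that nanoscale
structural signal.
"""

import numpy as np

from ipws.cubes import AcquisitionMeta
from ipws.phantom import make_ensemble, render_spectral
from ipws.roistats import roi_summary
from ipws.structure import compute_sigma_s

meta = AcquisitionMeta(
    wavelengths=tuple(np.linspace(500, 700, 101)), exposure_time=0.035,
    frame_interval=0.035, n_frames=101, pixel_size=0.1,
    medium_refractive_index=1.46)

ens = make_ensemble(50, 0.001, (64, 64), meta, medium_viscosity=0.219,
                    rng=np.random.default_rng(13))
cube = render_spectral(ens.positions, ens, meta, (64, 64))
smap = compute_sigma_s(cube, detrend_mode="mean")

mean, sem, n = roi_summary(smap.sigma_s, np.ones((64, 64), dtype=bool))
print(f"spheres             : {ens.n_scatterers}")
print(f"Sigma_s mean +- SEM : {mean:.2e} +- {sem:.1e}  (n = {n} pixels)")
print(f"Sigma_s max         : {np.nanmax(smap.sigma_s):.2e}")
print("Pixels near a sphere carry strong spectral fringes (high Sigma_s); "
      "empty regions are flat. Doubling the scattering amplitude would "
      "double Sigma_s.")
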