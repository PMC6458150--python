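# Methods

## The measurement model

A dual-mode interference microscope images the light backscattered by a
sample sitting on a high-refractive-index substrate.  The strong specular
reflection at the substrate–medium interface acts as a reference arm; the
weak field scattered by nanoscale refractive-index fluctuations inside the
sample interferes with it, which amplifies signals from structures far
below the diffraction limit.  Two acquisitions probe two different axes of
that interference:

* a **spectral cube** `I(λ, x, y)` scanned over 500–700 nm at one time
  point.  A scatterer at depth `z` imprints an oscillation
  `cos(2kz + φ)` on the spectrum (`k = 2πn/λ` in the medium); the
  per-pixel standard deviation of the detrended spectrum, **Σ_s**, grows
  with the amplitude of sub-diffraction refractive-index heterogeneity.
* a **temporal cube** `I(t, x, y)` at a single wavelength.  Motion of the
  scatterers modulates the interference phase `2kz(t)`, so the
  time-varying reflectance `δI(t)` (the trace minus its temporal mean)
  encodes macromolecular dynamics.

From the temporal cube three quantities are computed:

* **Σ_t²**, the per-pixel variance of `δI` over the acquisition, with the
  spatial-mean variance of an empty-field reference cube subtracted to
  remove the instrument-noise floor.  Σ_t² is proportional to the
  *fractional moving mass* `m_f = m_c·Φ` (typical moving-cluster mass
  times mobile volume fraction); with the default calibration constant of
  1, `m_f` is reported in normalized units because the absolute
  proportionality depends on instrument calibration.
* **D**, from the decay of the temporal autocorrelation.  For Brownian
  scatterers the normalized ACF is `exp(−4k²Dτ)`; backscattering doubles
  the optical phase (`2kz`), hence `4k²`.  Equivalently `D = 1/(4k²·t_c)`.
* **event timing**, a per-pixel single-changepoint scan that localizes an
  abrupt switch from quiescence to large-amplitude fluctuation (a
  "cellular paroxysm") at single-frame resolution.

## The diffusion estimator

The whole-field estimator follows an eleven-step sequence: normalize the
raw counts; subtract the per-pixel temporal mean; compute the biased (1/N)
autocovariance per pixel by zero-padded FFT; discard pixels whose ACF(0)
falls below √2 times the background ACF(0) (background = spatial-mean ACF
of the empty-field reference); subtract the mean background ACF from every
pixel; normalize each ACF to one at lag zero; aggregate across pixels;
truncate at the first non-positive value; take a two-point slope of the
log-ACF; and convert with `D = −slope/(4k²)`.

Two conventions in that sequence are genuinely open, and the package's
defaults were fixed by analysis of estimator bias rather than taken on
faith:

**Slope lags.**  With the phantom acquisition settings the exposure equals
the frame interval, and boxcar integration of an exponential ACF has a
clean structure: lag 0 is attenuated by `f(x) = 2x⁻²(x−1+e⁻ˣ)`
(`x` = exposure/t_c) while every lag ≥ τ₁ is multiplied by one common
constant.  A slope from lag 0 to lag 1 therefore carries a bias
`ln(g/f)/τ₁` that reaches tens of percent when `x ≈ 1`, and lag 0 also
holds all the white detector-noise variance.  The default slope is taken
between lags 1 and 2, where the decay is exactly exponential and both the
exposure factor and the normalization cancel; `slope_lags=(0, 1)` remains
available.

**Cross-pixel aggregation.**  Averaging `ln(ACF)` across pixels (a
geometric mean) is only unbiased when each per-pixel ACF estimate is
nearly noiseless.  At 201 frames the per-pixel estimates at the slope lags
have relative errors approaching one for fast decays, and the log-average
acquires a Jensen bias that steepens the apparent decay — measured at
+5…+30% on both rendered phantoms and exact AR(1) ensembles.  The default
aggregation is therefore arithmetic: the spatial mean of the normalized
ACFs (an unbiased estimate of the ensemble ACF) is computed first and the
log is taken of the averaged curve.  `acf_average="geometric"` reproduces
the log-average for comparison.

The per-pixel map path replaces cross-pixel averaging with a per-lag
spatial Gaussian filter (default σ = 2 px) before normalization,
truncation and the per-pixel two-point slope; σ = 0 reproduces the
unsmoothed path exactly.  The whole-field path applies no spatial filter.

**Exposure correction** divides a measured variance by `f(x)` above.  It
is applied for Σ_t comparisons against theory (where `t_c` is known from
the condition) and not for D estimation, where the lag-1/lag-2 slope is
already exposure-independent.

**Sensitivity window.**  The bracketing convention `t_c ∈ [T_exp, ΔT]`
gives `D_max = 1/(4k²T_exp)` and `D_min = 1/(4k²ΔT)` — 2.8×10⁻² and
1.4×10⁻⁴ µm²/s at the phantom settings.  The convention string is recorded
with every result; no claim is made that other published bounds derived
from different conventions are reproduced.

## The phantom simulator

The simulator is scalar and first-Born: spheres of radius 25–100 nm are
deep in the Rayleigh regime, so each contributes a field
`a·W(p−x_j)·exp(i(2kz_j+φ_j))` with amplitude `a ∝ r³(n_s²−n_m²)`
(default prefactor 0.07, giving `a ≈ 0.03` for a 100 nm polystyrene
sphere against √R_ref ≈ 0.096 — safely heterodyne) and a fixed random
phase per sphere.  Intensity is `|√R_ref + Σ…|²` with
`R_ref` the Fresnel reflectance of the sapphire–glycerol interface
(≈ 0.0092).

* **Lateral weight.**  `W` is Gaussian with σ = 0.21·λ/NA using the
  *illumination* NA (0.55 → σ ≈ 0.21 µm): the heterodyne term is the
  overlap of the scattered field with the reference mode, which is set by
  the illumination optics.  A collection-NA kernel (σ ≈ 0.08 µm) would add
  a lateral-transit decay channel of order `1/(4k²σ²) ≈ 10%` of the axial
  rate and break the `exp(−4k²Dτ)` law the simulator must obey; with the
  reference-mode kernel the residual lateral contribution is ≈ 2%.
* **Geometry.**  Lateral positions are periodic over the field of view and
  the PSF convolution is circular, so the ensemble is exactly stationary
  over arbitrarily long acquisitions.  Spheres are placed uniformly over a
  4 µm axial window (~1.5 depths of field of the NA-0.55 reference mode,
  dof = nλ/NA² ≈ 2.65 µm) and diffuse freely in z thereafter.
* **Motion.**  Free 3-D Brownian steps with per-axis variance `2D·dt`,
  `D` from Stokes–Einstein at 298.15 K with glycerine-table viscosities
  (90% w/w: 0.219 Pa·s; 70%: 0.0227 Pa·s at 25 °C).
* **Exposure.**  The detector integrates intensity: each frame averages at
  least 10 substep intensities across the exposure window, rising to 20
  when the correlation time is shorter than a quarter of the exposure.
* **Noise.**  Poisson shot noise at a photon budget of 4×10⁵ photons per
  pixel per frame at the reference level, 2-count read noise, and a
  multiplicative AR(1) LED drift (SD 2×10⁻³, 1 s correlation time) common
  to all pixels.  The photon budget emulates a high-SNR heterodyne
  detection; it and the amplitude prefactor are recorded in every
  ground-truth manifest.
* **Analytic variance.**  The expected spatial-mean Σ_t² is
  `2·R_ref·a²·N·⟨Σ_p W²⟩/n_pixels`, evaluated with the same discrete
  kernel (bilinear deposition ⊛ Gaussian) the renderer uses, so the
  Σ_t comparison tests the measurement chain, not a hand-waved formula.

What the generator does *not* emulate: Mie/vectorial scattering, multiple
scattering, optical aberrations, camera nonlinearity or gain structure,
the spatial heterogeneity and active (non-thermal) dynamics of real
chromatin, and photobleaching/phototoxicity.  Passing validation therefore
demonstrates that the estimators invert the stated forward model at
realistic noise levels — not that live-cell values are absolutely
calibrated.

## Changepoint detection

Each pixel trace is scanned exhaustively for a single split minimizing the
summed Gaussian negative log-likelihood with segment-wise mean *and*
variance (observed bursts shift both).  A change is accepted when the
improvement over the no-change model exceeds a BIC-like penalty
`c·3·ln(n)` on the twice-log-likelihood scale (three extra parameters).
The coefficient `c = 1.3` was fixed by null calibration: on 201-frame
stationary Gaussian noise the detector fires in ≈ 0.6% of traces
(contract: < 5%), while 3× variance steps are detected in > 99% of traces
with a median onset error of one frame.  Minimum segment length is 3
frames; pixels are processed independently (maps show per-pixel timing,
with no spatial regularization).

The synchrony report measures the maximum pairwise distance among pixels
sharing the earliest onset frame (convex hull for large sets) and converts
it to the diffusion rate a hypothetical messenger would need via
`D = L²/(2d·t)` with the planar convention `d = 2` by default; the
convention is recorded because the bound scales by only 3× across
`d ∈ {1,2,3}`.

## Validation suite and problem sizes

`run_phantom_validation` simulates five seeded replicates of each of eight
conditions (radii 25/37.5/50/100 nm at 0.1% volume fraction in 90%
glycerol and 0.3% in 70% glycerol; 201 frames × 32 ms at 550 nm) on a
64×64-pixel field (0.1 µm pixels), a size at which per-condition
Monte-Carlo scatter is a few percent while the whole suite runs in a few
minutes on one CPU.  Diffusion is validated on the 0.1%/90% suite only:
the 0.3%/70% spheres (t_c ≈ 2–10 ms) decay faster than the 32 ms exposure
resolves, which attenuates Σ_t recoverably but biases D irrecoverably —
so their Σ_t enters the comparison and their D does not.  R² compares
per-condition replicate means (the bar-height statistic of a
replicate-averaged comparison); the mean absolute percent error averages
over individual condition-seed cubes.

Residual D biases of order +5–15% remain at 201 frames.  They are
finite-trace effects of the prescribed estimator, dominated by the
sample-mean subtraction (the bias shrinks about fourfold when traces are
four times longer) plus the ~2% lateral-transit term, and they are the
same in kind for any instrument acquiring 201-frame traces at these
correlation times.

## Numerical choices and degenerate inputs

* ACF estimator: biased (1/N) autocovariance — stable at large lags,
  standard in dynamic light scattering.
* Negative-value handling: curves are truncated at the first non-positive
  lag (uniform lag spacing is preserved for the log); negative
  reference-subtracted variances are clamped to zero and masked invalid.
* `f(x)` is evaluated by series below `x = 10⁻⁴` to avoid cancellation.
* Population (divide-by-N) convention for Σ_s and Σ_t²; sample (N−1)
  convention for SEMs across pixels or replicates.
* Constant traces: the changepoint detector returns "no event"; zero
  paired differences give `t = 0, p = 1`.
* All randomness flows through explicit `numpy` Generators seeded from a
  single `SeedSequence`; identical seeds give bit-identical cubes, tables
  and reports.

## Known limitations

* `m_f` has no absolute mass calibration; only ratios and percent changes
  are meaningful without an instrument-specific constant.
* The D map path (per-pixel log slopes after spatial smoothing) inherits a
  positive noise bias relative to the whole-field path; map values are for
  spatial contrast, the scalar `mean_D` for quantitative comparisons.
* The sensitivity window is a convention, not a hard cutoff; estimates
  near its edges degrade gradually.
* Single-changepoint search only: a trace with several regime switches
  reports the dominant one.
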