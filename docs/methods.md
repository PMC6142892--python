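# Methods

`imsdkit` extracts the structural (size) and dynamic (diffusivity, mode of
motion) properties of sub-cellular organelles — endosomes, lysosomes and
similar bright, mobile, near-diffraction-limited structures — from
time-lapse fluorescence image stacks. Its central estimator is the
imaging-derived mean square displacement (iMSD), obtained from
spatiotemporal correlation of intensity fluctuations without extracting any
trajectory; a single-particle-tracking (SPT) pipeline and direct image-based
sizing serve as independent cross-checks, and a synthetic-stack simulator
with exact ground truth closes the loop for validation.

## The correlation function and the iMSD

For a calibrated stack `I(x, y, t)` the spatiotemporal correlation is

    G(xi, chi, tau) = < dI(x, y, t) dI(x + xi, y + chi, t + tau) > / <I>^2

with `dI = I − <I>`, averaged over all pixel positions (periodic FFT
convention) and over every frame pair separated by `tau`. The implementation
computes per-frame spatial FFTs followed by a zero-padded FFT along time, so
every pair contributes exactly once; it matches the direct quadruple-sum
definition to floating-point precision (this equivalence is a test). The
mean subtracted is the grand (whole-stack) mean; per-frame subtraction is
available but also removes genuine particle-number fluctuations, so it is
not the default.

For diffusing particles imaged as Gaussian spots, `G` at each temporal lag
is approximately Gaussian in the spatial lags. Each lag slice is fit with

    G(xi, chi) = A exp(−(xi² + chi²) / sigma_r²) + y0,

written deliberately *without* a factor 2 in the denominator so that
`sigma_r²(tau)` itself is the iMSD and the Brownian law reads
`sigma²(tau) = sigma0² + 4 D tau`. With the factor-2 convention every
reported `D` and size would silently rescale. The zero-spatial-lag pixel
carries uncorrelated shot noise and is excluded from the fit (standard
fluctuation-spectroscopy practice; a flag re-includes it). For an emitter
whose rendered profile has Gaussian SD `s`, the intercept is
`sigma0² = 4 s²`; in terms of the 1/e radius `sigma_s = sqrt(2) s` this is
the familiar `2 sigma_s²`.

The iMSD curve is then fit with a diffusion-law model,

    brownian    sigma²(tau) = sigma0² + 4 D_M tau
    anomalous   sigma²(tau) = sigma0² + 4 D_M tau^alpha,

by bounded nonlinear least squares (`alpha` in [0.05, 2], flagged when it
lands on a bound), multi-started from a log–log regression of the curve's
increments. `D_M` is the long-range diffusivity (um²/s; generalized
um²/s^alpha for the anomalous model), `alpha` classifies the mode of motion
(>1 super-diffusive, <1 sub-diffusive), and `size = 1000·sqrt(sigma0²)` nm
is the intercept-derived average diameter, reported literally (no PSF term
is subtracted by default; an optional correction mode exists, because the
apparent size is the PSF-convolved one either way and is compared to
FWHM-based sizes measured on the same images).

### Numerical choices that matter

* **Relative-error weighting (default).** The statistical uncertainty of a
  fitted correlation width grows roughly in proportion to the width itself,
  so the diffusion-law fit uses `sigma ∝ sigma²(tau)` weights. Unweighted
  fits are dominated by the largest, least-certain long-lag points and
  proved unstable for fast diffusers (alpha excursions toward the bounds at
  D = 0.2 um²/s); `weights=None` restores the plain fit.
* **Adaptive per-lag fit radius (default).** Each lag's Gaussian fit is
  restricted to twice the width fitted at the previous lag (at least 5 px,
  capped at the computed spatial extent). Narrow early-lag peaks are then
  not drowned in far-lag noise, and the long-lag narrowing bias caused by
  particles leaving the field of view is reduced. A fixed radius is
  available.
* **Lag validity.** A lag is invalid when its Gaussian fit fails to
  converge or returns an unphysical width; invalid lags are excluded from
  model fits (at least 3 valid lags are required). Converged low-quality
  lags are *kept* by default: when a directed component out-runs the
  spatial fit domain, exactly those lags carry the saturation signal that
  suppresses the apparent alpha at long analysis windows. An optional
  per-lag r² threshold can reject them.
* **Fit windows.** The default temporal window is 10% of the acquisition
  (the value found to balance statistics against timescale mixing); the
  window analysis additionally reports 5% and 20%. The default spatial
  extent is ±10 px, a processing parameter the user should scale to the
  expected displacement (`sqrt(sigma0² + 4 D tau_max)`): the validation
  runs use ±48 px for Brownian diffusivities up to 0.2 um²/s, and keep
  ±10 px where the finite extent is the point (mode-of-motion windows).

## Time-window analysis

A single acquisition is analyzed over windows covering 5, 10 and 20% of its
duration (for 460 frames at 65 ms: lags up to 1.5, 3 and 6 s). Because the
iMSD is an average diffusion law, the fitted `(alpha, size, D_M)` triplet
depends on the observation timescale: motor-driven transport appears
super-diffusive on short windows, while crowding and confinement pull
`alpha` below 1 as the window grows. The triplets form a per-acquisition
"fingerprint" exported for population-level scatter plots.

## Single-particle tracking reference

Detection is a Laplacian-of-Gaussian filter at the scale of the expected
spot radius with local-maximum extraction and per-axis quadratic sub-pixel
refinement (adequate at organelle-imaging signal-to-noise; Gaussian PSF
fitting would be the next step in precision). Linking solves a padded
linear-assignment problem per frame (squared-displacement cost, non-link
alternative at the squared maximum link distance) with gap closing;
segment merging/splitting is not modelled — for sparse organelle fields
frame-to-frame optimal assignment is an internally consistent reference,
which is what the comparison needs. Trajectories lasting more than 12 s
(strict inequality) are retained. Per-trajectory MSDs are time-averaged
over all sample pairs at each true frame separation (gaps pair on real
separations); the ensemble MSD is their unweighted mean, and `D` comes from
a linear fit with a free offset over the first max(4, 10%) lags, mirroring
the iMSD default window.

On the same simulated stack the iMSD and the ensemble trajectory MSD are
required to agree: fitted diffusivities within 20%, and the motion parts of
the two curves (each minus its own fitted intercept) point-wise within 25%
over 0.5–3 s. The lower end of that comparison range skips the first few
lags where both motion parts are near zero and a ratio is dominated by
localization and fit noise.

## Image-based sizing

`profile_fwhm` samples the intensity along a user-chosen segment every
quarter pixel with cubic-spline interpolation and fits a Gaussian plus
constant; the FWHM `2 sqrt(2 ln 2) sigma` estimates the spot diameter.
(Bilinear sampling of a ~1.4 px-SD peak broadens the fit by ~4%, which is
why the interpolation is cubic.) `particle_diameters` thresholds the image
(half-maximum convention, so the disk-equivalent diameter is comparable to
the FWHM), labels 8-connected components, discards those below a minimum
area and reports `d = 2 sqrt(A/pi)` per component. Both are invariant to
intensity scaling and constant background.

## The synthetic-data generator

The simulator emulates the statistical structure of live-cell confocal
acquisitions of labelled organelles: 256×256-pixel 16-bit-scale frames,
69 nm pixels, 65–129 ms frame times, 400–1000 frames, a few tens of bright
diffusing spots on a dark background. Defaults describe a lysosome-like
acquisition: 30 particles, D = 0.05 um²/s, 460 frames at 65 ms, spot SD
150 nm, peak ≈ 400 counts over a ≈ 20-count background.

Motion models: Brownian (per-axis increment variance `2 D dt`); anomalous
via fractional Brownian motion with Hurst exponent `alpha/2` (Davies–Harte
circulant embedding, Cholesky fallback), scaled so the per-axis MSD is
exactly `2 D tau^alpha` — the standard generative choice that makes the
power law exact in expectation; confined Brownian motion reflected in a
square box of side `box_L` centred on each particle's start (a local cage);
and directed-plus-Brownian with a constant per-particle random heading.
Particles start uniformly in a field 20% larger than the view to avoid
edge depletion.

Rendering places each emitter as an isotropic Gaussian of SD
`emitter_sigma` at its continuous position; `emitter_sigma` is the
*post-PSF* spot width — organelle shape and PSF are not modelled separately
because the analysis only ever sees the convolved spot. Amplitudes decay as
`exp(−bleach_rate·t)`; pixel values are Poisson(signal + background) plus
Gaussian read noise, clipped at zero (analog-PMT excess noise is not
modelled separately). A single seed drives trajectories and noise through
independent sub-streams, so stacks are bit-reproducible.

What the simulator does *not* reproduce — intra-frame scan-time motion
blur, z-diffusion and optical sectioning, heterogeneous per-organelle
brightness and size, and spatially varying cellular background — bounds
what passing tests show: they validate the estimator chain on data whose
generative model is known, not the biology of any particular organelle.
The slow-imaging size artifact is reproduced through inter-frame motion
(a 10 s frame time samples a confined walker all over its cage, inflating
the apparent intercept size), not through intra-frame scanning geometry.

### Validation scenarios and their parameters

* **Brownian recovery.** D ∈ {0.01, 0.05, 0.2} um²/s spans slow endosomes
  to fast lysosome-like motion; 10 seeds per D; medians of `D_M` within 20%
  of truth and of `alpha` within 1 ± 0.1 at the 10% window, ±48 px extent.
* **Directed transport.** v = 0.3 um/s with D = 0.05 um²/s — an effective
  drift for intermittent motor-driven transport over a diffusive
  background. The drift crosses the ±10 px correlation domain between the
  5% and 10% windows, so the seed-averaged fitted `alpha` is >1 at 5% and
  decreases as the window grows: the finite spatial fit domain plays the
  role the crowded cytoplasm plays in real recordings.
* **Confinement.** box_L = 1 um with D = 0.05 um²/s plateaus the MSD within
  a second; `alpha` < 1 at the 20% window, and a 10 s/frame acquisition of
  the same system yields a strictly larger apparent size than the 65 ms
  one, while the 65 ms acquisition sizes within 15% of an immobile
  (fixed-sample-like) reference. Size comparisons across sampling rates use
  the linear (Brownian) intercept fit: on a fully decorrelated slow
  acquisition `alpha` is meaningless, and leaving it free lets the fit
  absorb the intercept into a steep `tau^alpha` term for some noise
  realizations.

## Known limitations

* The periodic FFT convention plus finite field of view censors large
  displacements, biasing long-lag iMSD values low by several percent; the
  weighting and adaptive radius mitigate but do not remove this.
* The anomalous exponent is fit within [0.05, 2]; strongly ballistic
  content saturates at the bound (reported via `alpha_at_bound`).
* Sub-pixel localization by quadratic interpolation is a known precision
  limit versus Gaussian-fit localization (~0.1 px at high SNR, worse near
  saturation).
* Intercept-derived sizes are PSF-convolved apparent diameters, not
  deconvolved physical sizes.
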