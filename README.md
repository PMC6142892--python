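# imsdkit

Structural and dynamic properties of sub-cellular organelles — average
size, long-range diffusivity and mode of motion — extracted from standard
live-cell time-lapse imaging, for cell biophysicists who have a confocal
stack of bright moving spots (endosomes, lysosomes, secretory granules)
and want numbers out of it without hand-curating trajectories.

## The method

The core estimator is the **imaging-derived mean square displacement
(iMSD)**. From a calibrated stack `I(x, y, t)` the spatiotemporal
correlation of intensity fluctuations is computed,

    G(ξ, χ, τ) = ⟨δI(x, y, t) · δI(x+ξ, y+χ, t+τ)⟩ / ⟨I⟩²,   δI = I − ⟨I⟩,

averaged over pixel positions (FFT convention) and over all frame pairs at
each temporal lag τ. For diffusing Gaussian spots each lag slice of G is
Gaussian in the spatial lags; fitting

    G(ξ, χ) = A · exp(−(ξ² + χ²)/σ_r²) + y₀

gives the iMSD curve σ²(τ) ≡ σ_r²(τ), the average diffusion law of every
imaged structure — no trajectories needed. A diffusion-law fit

    σ²(τ) = σ₀² + 4 D_M τ^α

then yields the long-range diffusivity **D_M**, the anomalous exponent
**α** (α = 1 Brownian, α > 1 directed transport, α < 1 crowding or
confinement), and the intercept **σ₀²**, whose square root estimates the
average apparent diameter of the imaged structures:
`size = 1000·√σ₀²` nm.

Because the iMSD is an average over the whole acquisition, analyzing the
same stack over growing time windows (5 / 10 / 20 % of its duration)
fingerprints how the apparent mode of motion depends on the observation
timescale.

Around the core, the package provides:

* `imsdkit.io` — TIFF frame series / multi-page TIFF reading with explicit
  calibration (pixel size, frame time), spreadsheet-style CSV + XLSX output;
* `imsdkit.simulate` — a synthetic stack generator (Brownian, fractional-
  Brownian anomalous, confined, directed motion; Gaussian emitters; Poisson
  + read noise; bleaching) with exact ground truth;
* `imsdkit.stics` / `imsdkit.imsd` — the correlation and iMSD analysis;
* `imsdkit.spt` — a single-particle-tracking reference pipeline (LoG
  detection, assignment linking, duration filter, trajectory/ensemble MSD);
* `imsdkit.sizing` — line-profile FWHM and segmented-particle diameters;
* `imsdkit.cli` — the `imsdkit` command with `simulate`, `run`, `spt`,
  `size` and `summary` subcommands.

## Worked example

Simulate a lysosome-like acquisition (30 particles, D = 0.05 µm²/s,
460 frames at 65 ms, 69 nm pixels, spot SD 150 nm) and analyze it:

```sh
imsdkit simulate --model brownian --D 0.05 --n-particles 30 \
    --frames 460 --seed 1 --out stack/
imsdkit run --input stack/ --label ly \
    --window-fractions 0.05,0.1,0.2 --spatial-extent 48 --out results/
```

which prints

```
[ly] window 0.05: D_M=0.05099 alpha=1.021 sigma0^2=0.0876 um^2 size=296 nm r^2=0.9999
[ly] window 0.1: D_M=0.05323 alpha=0.880 sigma0^2=0.07673 um^2 size=277 nm r^2=0.9979
[ly] window 0.2: D_M=0.04964 alpha=0.955 sigma0^2=0.08615 um^2 size=294 nm r^2=0.9974
```

Read: at every window the fitted diffusivity recovers the simulated
0.05 µm²/s within a few percent and α stays near 1 (Brownian motion has no
timescale). The intercept size ≈ 290–300 nm is the *apparent* (PSF-
convolved) diameter: the emitters were rendered with Gaussian SD
s = 150 nm, and the correlation of a spot with itself doubles the squared
width, so the expected intercept is σ₀² = 4 s² = 0.09 µm², i.e.
`size = 2 s = 300 nm`. The cross-check with tracking on the same stack,

```sh
imsdkit spt --input stack/ --label ly --radius-px 3 --out spt/
# -> 21 trajectories retained; ensemble D=0.05293 um^2/s (offset -0.004532 um^2, r^2=0.9999)
```

agrees with the iMSD diffusivity to ~4 % without either method seeing the
other's intermediate results. `results/` holds the correlation evolution,
the iMSD curve, fitted curves and parameters as CSVs plus `results.xlsx`,
a per-window `(α, size, D_M)` `fingerprint.csv`, the correlation stack as
a float TIFF, and a `manifest.json` recording every analysis default.

Real acquisitions are analyzed the same way: point `--input` at a
directory of `<prefix>_0001.tif … <prefix>_NNNN.tif` single-frame TIFFs
(or one multi-page TIFF) and give the calibration explicitly
(`--pixel-size`, `--frame-time`, or `--label ee/le/ly` for the built-in
defaults: 69 nm with 129 ms / 129 ms / 65 ms respectively). TIFF tags are
ignored on purpose.

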