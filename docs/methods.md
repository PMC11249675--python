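# Methods

`tfsofi` models and quantifies super-resolution optical fluctuation imaging
(SOFI) under temporal-focusing (TF) two-photon excitation. This note
records the model, its assumptions, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Imaging model

**Detection.** The detection point spread function (PSF) is a separable 3D
Gaussian parameterised by its lateral and axial FWHM (nm). A point source
laterally displaced from a pixel contributes the exact integral of the
unit-integral 2D Gaussian over the pixel area (computed with error
functions); a source defocused by `dz` is attenuated by the unit-peak axial
factor `exp(-dz² / 2σ_z²)`. The lateral width does **not** grow with
defocus in this model: defocused light is attenuated, not spread. This is a
deliberate simplification — it reproduces the axial mechanism that matters
here (the squared detection profile behind the SOFI sectioning curve, see
below) at the cost of photon conservation under defocus: the per-plane mean
signal of a scanned thin layer follows the axial response `g(z)` rather
than staying flat, unlike a real aplanatic system where defocus redistributes
photons laterally. Consequences for real data are discussed under
*Limitations*.

An `axial_fwhm_nm` must always be given explicitly (default study value
680 nm); no formula hides behind it. The theoretical lateral width uses the
standard wide-field approximation `FWHM = 0.51 λ_em / NA` (256.8 nm at
λ = 705 nm, NA = 1.4; `λ/2NA` would give 251.8 nm — both are within ~1.5 %
of each other and of typical printed values, and the choice is recorded in
output metadata).

**Temporal focusing.** The axial two-photon response is
`F(z) = offset + amplitude / (1 + a (z − z0)²)`, with sectioning parameter
`a` (1/µm²) and temporal-focus position `z0` (µm). The FWHM is `2/√a`
(half maximum where `a(z−z0)² = 1`); `a = 0` is the wide-field limit. `F`
already describes the *two-photon* signal, so the simulator applies it as a
single multiplicative weight on emitter brightness — no additional
squaring. How `a` follows from pulse duration, grating density, telescope
magnification, refractive index and wavelength is out of scope; `a` is a
model parameter, fitted or supplied. The additive offset exists for fitting
measured curves and is zero in the forward model.

**Excitation geometry.** The grating is imaged onto the sample by the tube
lens + objective 4f telescope: demagnification `f_TL / f_obj`, illuminated
field `beam diameter / demagnification`. With the default geometry (400 mm
tube lens, 2 mm objective focal length from the 200 mm reference tube
length / 100× convention, 8 mm beam) this gives 200× and a 40 µm field.

**Blinking.** Emitters switch between ON and OFF as a discrete-time
two-state Markov chain sampled once per frame, started from its stationary
distribution, independent across emitters and across z positions (each z is
a separate recording). Default per-frame switching probabilities are
0.5/0.5 (ON fraction 0.5). The 1 ms exposure is treated as short compared
to dwell times: frames are entirely ON or OFF, with no partial-frame
mixing and no power-law (heavy-tailed) dwell statistics. An optional
exponential envelope `exp(-rate · t)` on the photon expectation emulates
photobleaching for testing the trend diagnostic.

**Camera.** Photon-number-resolving readout: Poisson shot noise on the
expected photon image, additive camera offset, Gaussian read noise (default
0.3 counts), optional integer rounding, and a clamp to [0, 200] counts
(the dynamic range of the photon-resolving mode). Default emitter
brightness in the studies is 1000 detected photons per ON frame — about 25
counts in the peak pixel at the 46 nm sample pixel (4.6 µm camera pixel /
100×), comfortably inside the dynamic range.

## SOFI estimators

Per pixel, on the intensity trace `I(t)` with `δ = I − mean(I)`:

* order 2, lag 0: unbiased variance `Σδ² / (n−1)`;
* order 2, lag τ: `Σ δ(t)δ(t+τ) / (n−τ−1)`;
* order 3: `n Σδ³ / ((n−1)(n−2))` (third k-statistic).

Unbiased k-statistics make the small worked examples exact. Cumulants of
independent sources add; constants vanish (background elimination); scaling
frames by `c` scales orders 2/3 by `c²`/`c³`; for a Gaussian PSF the
order-N image raises the PSF to the N-th power, shrinking its FWHM by √N.

The **lag-0 variance carries a shot-noise bias**: Poisson noise contributes
its mean, so a second-order image is
`(A·psf)² p(1−p) + A·psf·p + const` — a squared-PSF term plus a *wider*
term shaped like the PSF itself. Lag ≥ 1 removes the bias (Poisson draws
are independent across frames) but also loses signal when blinking is
uncorrelated frame-to-frame; lag 0 remains the default and the bias is
accounted for in the interpretation of the studies (below). Cross-cumulants
(virtual pixels), orders ≥ 4, cusp-artifact correction and deconvolution
post-processing are out of scope.

**Fluctuation diagnostic.** To confirm that contrast comes from blinking
rather than slow drifts such as bleaching, each pixel's trace is regressed
on frame index; the fraction of variance explained by the linear trend
(R²) is summarised by its median over signal-bearing pixels (robust
background cut: per-pixel mean above median + 5 scaled MAD, falling back to
all pixels if none pass). Median < 0.5 → "fluctuation-dominated". The
threshold is a convention; single bright pixels with strong blinking can
stay fluctuation-dominated under bleaching, but dense bright regions (many
emitters, fluctuations averaging out) flip to trend-dominated, which is the
regime where bleaching corrupts SOFI volumes.

## Quantification

**Sectioning curves.** Cumulant (or mean) images per defocus are summed
within 8 equal rectangular regions (2×4 grid; configurable). The curve
value is the across-region mean, the uncertainty the across-region standard
deviation — region-to-region emitter-density variation therefore dominates
the error bars near the peak.

**Fits.** `F(z)` (for TF / intensity curves) or Gaussian + offset (for SOFI
curves) by least squares (`scipy.optimize.curve_fit`), initialised from the
curve extrema (centre at the argmax, ties to lower z; amplitude max−min;
offset min; width half the z range). FWHM conventions: `2/√a` and
`2√(2 ln 2) σ`. Inverse-variance weighting from the curve uncertainties is
available (`weighted=True`, the default) and is the right choice when the
model is exact, as for synthetic TF curves with multiplicative noise. For
**SOFI sectioning curves it is disabled** in the analysis chain: background
points have near-zero across-region spread while the Gaussian model omits
the shot-noise pedestal, so weighting pins the fit to the wings and inflates
the width by ~20 % on the study conditions; unweighted fitting keeps the
estimate peak-dominated. Non-convergence returns an explicit failure record
rather than raising.

**PSF statistics.** Local maxima above `background + 5 × robust noise`
(median / scaled MAD; for strictly noiseless synthetic images the threshold
falls back to 5 % of the dynamic range), minimum mutual separation with the
brighter peak kept, border exclusion, then a 2D Gaussian + offset fit in a
7×7-pixel window per peak; FWHM from the mean of the two lateral sigmas.
Reported as mean ± standard deviation over emitters. The resolution-
improvement ratio propagates the two standard deviations to first order.

## Validation studies and what they show

The canonical studies (`tfsofi.studies`, also run by
`scripts/acceptance.py`) use the acquisition the simulator emulates: 300
frames × 1 ms per position, 46 nm pixels, ON fraction 0.5, 1000
photons/frame ON, read noise 0.3 counts, 200-count clamp.

* **TF fit recovery** — noisy synthetic `F(z)` curves (a = 0.666 1/µm²,
  z ∈ [−6, 6] µm, 0.25 µm steps, 5 % multiplicative noise per region, 20
  repetitions) recover the 2.45 µm FWHM well within ±0.3 µm.
* **Lateral resolution** — 20 isolated in-focus emitters (jittered grid,
  ≥2 µm apart, 256×256 px): the order-2 image fits to ≈198 nm against the
  √2 expectation 274/√2 = 193.7 nm; the few-nm excess is the lag-0
  shot-noise term, and the value sits inside the 199 ± 12 nm reference
  interval. The mean image recovers 274 nm.
* **Axial sectioning** — 200 emitters in one plane (96×96 px, 4.4 µm
  field, ≈10 µm⁻²), scanned −1.5…1.5 µm in 50 nm steps, 5 seeds: the
  summed order-2 curve fits to ≈506 nm. The mechanism value is
  680/√2 = 480.8 nm (verified to <5 % with shot noise disabled); the ≈5 %
  excess is again the shot-noise pedestal, whose relative amplitude is
  `1/(A(1−p) Σpsf²) ≈ 0.16` at 1000 photons/frame and which a Gaussian fit
  partially absorbs into its width. Suppressing it would need either
  brightness well beyond the camera's 200-count range or a lag/shot-
  corrected estimator. Under TF excitation (a = 0.666 1/µm²) the same scan
  fits ≈25 nm narrower — the TF weight multiplies the brightness, the
  cumulant squares it, and it suppresses the pedestal — so in this model TF
  slightly *sharpens* the apparent SOFI sectioning rather than leaving it
  identical; at bench noise levels (±14 nm error bars) such a shift is a
  ~2σ effect.

Problem sizes (field sizes, 5–20 repetitions) were chosen so the full
validation runs on a single CPU in minutes.

## Limitations

* Fixed-width attenuating PSF: no defocus blur, no photon conservation
  under defocus, no Born–Wolf/vectorial model, no aberrations or
  scattering. Sectioning numbers for the *mean* image of a thin layer
  reflect `F(z)·g(z)`, not `F(z)` alone.
* Two-state Markov blinking with per-frame switching; real quantum dots
  show power-law dwell times and partial-frame mixing.
* No emitter drift, no rolling shutter, no pixel-response nonuniformity.
* Passing the synthetic studies shows the estimators and fits implement
  the stated model correctly and that the √N mechanism behaves as derived;
  it does not certify performance on real samples with aberrated PSFs,
  correlated backgrounds or heavy-tailed blinking.
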