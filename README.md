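# tfsofi

Super-resolution optical fluctuation imaging (SOFI) with temporal-focusing
(TF) two-photon excitation: a forward simulator of blinking-emitter movies
and the full quantification chain — temporal-cumulant images, axial
sectioning curves, and PSF-FWHM statistics.

## The problem

SOFI turns the blinking of fluorescent emitters (e.g. quantum dots) into
resolution: independent emitters fluctuate independently, so the temporal
cumulant of each pixel's intensity trace builds an image in which a
Gaussian detection PSF is raised to the N-th power — its FWHM shrinks by
√N for cumulant order N, and any non-fluctuating background (out-of-focus
light) vanishes. Being wide-field, SOFI struggles in thick, dense samples;
temporal focusing — wide-field two-photon excitation in which a grating
disperses the spectral components of a femtosecond pulse so it is
compressed, and two-photon excitation efficient, only near the focal
plane — confines the excitation to a thin slice with axial response

    F(z) = offset + amplitude / (1 + a (z − z0)²),    FWHM = 2/√a,

reducing out-of-focus bleaching and background. `tfsofi` is for
microscopists and method developers who want to simulate such acquisitions
(two-state Markov blinking, pixel-integrated Gaussian PSF, TF excitation
weight, photon-number-resolving camera with Poisson + read noise and a
200-count clamp) and to quantify them the way a bench characterisation
would:

* order-2/3 temporal cumulant images (unbiased k-statistics, optional
  time lag) and a fluctuation-vs-bleaching trend diagnostic;
* sectioning curves — cumulant images summed over 8 regions per defocus,
  with across-region standard deviations — fitted with `F(z)` or a
  Gaussian (`FWHM = 2√(2 ln 2) σ`);
* per-emitter lateral PSF FWHM from windowed 2D Gaussian fits, and the
  SOFI/widefield resolution-improvement ratio with propagated uncertainty.

## Worked example

Simulate isolated blinking quantum dots (300 frames × 1 ms, 46 nm pixels,
detection FWHM 274 nm lateral / 680 nm axial), compute SOFI, and measure
the PSF:

```sh
$ cat examples/spots.yaml
seed: 7
psf: {lateral_fwhm_nm: 274.0, axial_fwhm_nm: 680.0}
sample: {kind: flat_layer, n_emitters: 15, field_um: 8.0, brightness: 1000.0}
plan:
  n_frames: 300
  frame_shape: [176, 176]
  pixel_size_nm: 46.0
  z_positions_um: [0.0]

$ tfsofi simulate --config examples/spots.yaml --out spots
$ tfsofi sofi --input spots/movie.tif --out spots_sofi
$ tfsofi psf --input spots_sofi/mean.tif       --out psf_mean --pixel-size-nm 46 --min-separation-nm 800
PSF FWHM: 274.2 +/- 6.6 nm (11 emitters)
$ tfsofi psf --input spots_sofi/sofi_order2.tif --out psf_sofi --pixel-size-nm 46 --min-separation-nm 800
PSF FWHM: 197.3 +/- 4.5 nm (11 emitters)
```

The mean-intensity image reproduces the 274 nm detection PSF; the
second-order SOFI image is √2 narrower (274/√2 = 193.7 nm, plus a few nm
from the shot-noise term of the lag-0 variance).

Axial sectioning of a thin quantum-dot layer scanned through the temporal
focus (TF sectioning parameter a = 0.666 µm⁻², 61 steps of 50 nm):

```sh
$ tfsofi simulate --config examples/layer.yaml --out scan   # excitation: {mode: tf}
$ tfsofi zscan-analyze --input scan/index.csv --out analysis
SOFI sectioning FWHM: 481.1 nm (gaussian)
mean intensity sectioning FWHM: 622.1 nm (eq1_lorentzian_form)
$ tfsofi diagnose --input scan/z030.tif --out diag
verdict: fluctuation-dominated (median trend fraction 0.001)
```

The summed SOFI signal is confined to a ~0.48 µm slice — the squared
axial response — while the mean intensity follows the broader product of
the TF profile and the detection response; the diagnostic confirms the
contrast comes from blinking, not drifts.

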