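"""Quantification of sectioning curves and PSF widths.

Implements the measurement chain used to characterise TF-SOFI on a thin
emitter layer scanned through focus:

* ``summed_signal_curve`` — per-defocus summed signal averaged over equal
  rectangular regions of the field, with the across-region standard
  deviation as the uncertainty;
* ``fit_tf_sectioning`` — weighted least-squares fit of the TF axial
  response ``offset + amplitude / (1 + a (z - z0)^2)``, FWHM ``2/sqrt(a)``;
* ``fit_gaussian_sectioning`` — weighted Gaussian + offset fit, FWHM
  ``2 sqrt(2 ln 2) sigma`` (describes the SOFI sectioning curve);
* ``estimate_psf_fwhm`` — emitter-wise lateral FWHM statistics from
  windowed 2D Gaussian fits around isolated peaks;
* ``resolution_improvement`` — FWHM ratio with first-order error
  propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

from .optics import FWHM_PER_SIGMA, fwhm_from_sectioning_parameter

__all__ = [
    "SectioningCurve",
    "CurveFit",
    "PsfStats",
    "NoQualifyingPeaksError",
    "summed_signal_curve",
    "fit_tf_sectioning",
    "fit_gaussian_sectioning",
    "estimate_psf_fwhm",
    "resolution_improvement",
]


@dataclass
class SectioningCurve:
    """Summed signal versus defocus with across-region uncertainties."""

    z_um: np.ndarray
    signal: np.ndarray
    uncertainty: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        if not (len(self.z_um) == len(self.signal) == len(self.uncertainty)):
            raise ValueError("z, signal and uncertainty must share one length")
        if len(self.z_um) > 1 and not np.all(np.diff(self.z_um) > 0):
            raise ValueError("z values must be strictly increasing")
        if np.any(self.uncertainty < 0):
            raise ValueError("uncertainties must be >= 0")


@dataclass
class CurveFit:
    """Fitted axial-response model and the FWHM it implies."""

    model: str  # "eq1_lorentzian_form" or "gaussian"
    parameters: dict
    uncertainties: dict
    fwhm_um: float
    residual_norm: float
    success: bool = True
    message: str = ""


@dataclass
class PsfStats:
    """Per-emitter lateral FWHM measurements and their mean +/- std (nm)."""

    fwhm_nm: np.ndarray
    mean_fwhm_nm: float
    std_fwhm_nm: float
    n_emitters: int
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fwhm_nm = np.asarray(self.fwhm_nm, dtype=float)
        if self.n_emitters < 1:
            raise ValueError("PsfStats requires at least one emitter")
        if self.std_fwhm_nm < 0:
            raise ValueError("std_fwhm_nm must be >= 0")


class NoQualifyingPeaksError(RuntimeError):
    """No isolated peak survived detection / isolation / fitting."""


def _region_grid(n_regions: int) -> tuple[int, int]:
    """Near-square (rows, cols) factorisation with rows <= cols; 8 -> (2, 4)."""
    rows = int(math.sqrt(n_regions))
    while n_regions % rows:
        rows -= 1
    return rows, n_regions // rows


def summed_signal_curve(
    images: list[np.ndarray],
    z_um,
    n_regions: int = 8,
    region_grid: tuple[int, int] | None = None,
) -> SectioningCurve:
    """Summed signal per defocus, averaged over equal rectangular regions.

    The field is partitioned into ``n_regions`` equal tiles (default a
    2 x 4 grid for 8 regions).  Per z position the signal is summed within
    each tile; the curve value is the mean across tiles and the uncertainty
    the across-tile standard deviation.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    grid = region_grid if region_grid is not None else _region_grid(n_regions)
    gr, gc = grid
    if gr * gc != n_regions:
        raise ValueError("region_grid must tile exactly n_regions tiles")
    images = [np.asarray(im, dtype=float) for im in images]
    z = np.asarray(z_um, dtype=float)
    if len(images) != len(z):
        raise ValueError("one image per z position required")
    shape = images[0].shape
    if any(im.shape != shape for im in images):
        raise ValueError("all images must share one shape")
    if shape[0] % gr or shape[1] % gc:
        raise ValueError(
            f"image shape {shape} is not tiled by a {gr}x{gc} region grid"
        )
    th, tw = shape[0] // gr, shape[1] // gc
    signal = np.empty(len(z))
    unc = np.empty(len(z))
    for k, im in enumerate(images):
        tiles = im.reshape(gr, th, gc, tw).sum(axis=(1, 3)).ravel()
        signal[k] = tiles.mean()
        unc[k] = tiles.std(ddof=0)
    return SectioningCurve(z, signal, unc, n_regions)


def _weights(curve: SectioningCurve, weighted: bool) -> np.ndarray | None:
    """Per-point sigma for the fit: the curve uncertainties when requested
    and all positive (inverse-variance weighting), else unweighted.

    ``weighted=False`` is appropriate when the fitted model is known to be
    incomplete far from the peak (e.g. the shot-noise pedestal of a lag-0
    SOFI curve) while the background points carry deceptively small
    uncertainties; inverse-variance weighting would then pin the fit to the
    model-misfit region.
    """
    if weighted and np.all(curve.uncertainty > 0):
        return curve.uncertainty
    return None


def _initial_guesses(curve: SectioningCurve) -> tuple[float, float, float, float]:
    """amplitude, z0, half-range width scale, offset (ties broken to lower z)."""
    s = curve.signal
    z0 = float(curve.z_um[int(np.argmax(s))])
    amp = float(s.max() - s.min())
    off = float(s.min())
    width = float(max(np.ptp(curve.z_um) / 2.0, np.finfo(float).eps))
    return amp, z0, width, off


def fit_tf_sectioning(curve: SectioningCurve, weighted: bool = True) -> CurveFit:
    """Fit the TF axial response ``offset + amplitude / (1 + a (z - z0)^2)``.

    Weighted least squares (inverse-variance from the curve uncertainties
    when available and ``weighted``).  The FWHM is ``2 / sqrt(a)``.
    """
    if len(curve.z_um) < 4:
        raise ValueError("need at least 4 points spanning the peak")
    amp0, z00, width0, off0 = _initial_guesses(curve)
    a0 = 4.0 / width0**2

    def model(z, amplitude, z0, a, offset):
        return offset + amplitude / (1.0 + a * (z - z0) ** 2)

    try:
        popt, pcov = curve_fit(
            model,
            curve.z_um,
            curve.signal,
            p0=[amp0 if amp0 > 0 else 1.0, z00, a0, off0],
            sigma=_weights(curve, weighted),
            bounds=([0.0, -np.inf, 0.0, -np.inf], np.inf),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return CurveFit("eq1_lorentzian_form", {}, {}, float("nan"), float("nan"),
                        success=False, message=f"fit failed: {exc}")
    perr = np.sqrt(np.diag(pcov))
    amplitude, z0, a, offset = popt
    if a <= 0:
        return CurveFit("eq1_lorentzian_form",
                        dict(zip(("amplitude", "z0_um", "a_per_um2", "offset"), popt)),
                        {}, float("nan"), float("nan"),
                        success=False, message="fitted a <= 0: no finite FWHM")
    resid = curve.signal - model(curve.z_um, *popt)
    return CurveFit(
        model="eq1_lorentzian_form",
        parameters={"amplitude": amplitude, "z0_um": z0, "a_per_um2": a, "offset": offset},
        uncertainties=dict(zip(("amplitude", "z0_um", "a_per_um2", "offset"), perr)),
        fwhm_um=fwhm_from_sectioning_parameter(a),
        residual_norm=float(np.linalg.norm(resid)),
    )


def fit_gaussian_sectioning(curve: SectioningCurve, weighted: bool = True) -> CurveFit:
    """Fit ``offset + amplitude * exp(-(z - z0)^2 / (2 sigma^2))``; the FWHM
    is ``2 sqrt(2 ln 2) sigma``.  Describes the SOFI sectioning curve.

    See :func:`_weights` for when ``weighted=False`` is the better choice.
    """
    if len(curve.z_um) < 4:
        raise ValueError("need at least 4 points spanning the peak")
    amp0, z00, width0, off0 = _initial_guesses(curve)

    def model(z, amplitude, z0, sigma, offset):
        return offset + amplitude * np.exp(-((z - z0) ** 2) / (2.0 * sigma**2))

    try:
        popt, pcov = curve_fit(
            model,
            curve.z_um,
            curve.signal,
            p0=[amp0 if amp0 > 0 else 1.0, z00, width0 / 2.0, off0],
            sigma=_weights(curve, weighted),
            bounds=([0.0, -np.inf, 1e-12, -np.inf], np.inf),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return CurveFit("gaussian", {}, {}, float("nan"), float("nan"),
                        success=False, message=f"fit failed: {exc}")
    perr = np.sqrt(np.diag(pcov))
    amplitude, z0, sigma, offset = popt
    resid = curve.signal - model(curve.z_um, *popt)
    return CurveFit(
        model="gaussian",
        parameters={"amplitude": amplitude, "z0_um": z0, "sigma_um": sigma, "offset": offset},
        uncertainties=dict(zip(("amplitude", "z0_um", "sigma_um", "offset"), perr)),
        fwhm_um=FWHM_PER_SIGMA * abs(sigma),
        residual_norm=float(np.linalg.norm(resid)),
    )


def _gauss2d(coords, amplitude, r0, c0, sigma_r, sigma_c, offset):
    r, c = coords
    return (
        offset
        + amplitude
        * np.exp(-((r - r0) ** 2) / (2 * sigma_r**2) - (c - c0) ** 2 / (2 * sigma_c**2))
    ).ravel()


def estimate_psf_fwhm(
    image: np.ndarray,
    pixel_size_nm: float,
    min_separation_nm: float = 800.0,
    snr_threshold: float = 5.0,
    window: int = 7,
) -> PsfStats:
    """Emitter-wise lateral FWHM from isolated peaks of an image.

    Local maxima above ``background + snr_threshold * robust noise`` (median
    and scaled MAD) are detected; peaks closer than ``min_separation_nm`` to
    a brighter peak, or too close to the border for a full fit window, are
    discarded.  A 2D Gaussian + offset is fitted in a ``window x window``
    pixel region around each survivor and the mean sigma of the two lateral
    axes is converted to a FWHM.  Returns per-emitter FWHMs plus their
    mean +/- standard deviation.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be > 0")
    half = window // 2
    bg = float(np.median(image))
    noise = 1.4826 * float(np.median(np.abs(image - bg)))
    if noise == 0.0:
        # noiseless synthetic image: fall back to a fraction of the dynamic range
        noise = 0.05 * (float(image.max()) - bg) / max(snr_threshold, 1.0)
    min_distance = max(int(np.ceil(min_separation_nm / pixel_size_nm)), 1)
    peaks = peak_local_max(
        image,
        min_distance=min_distance,
        threshold_abs=bg + snr_threshold * noise,
        exclude_border=half,
    )
    fwhms = []
    centers = []
    for pr, pc in peaks:
        sub = image[pr - half : pr + half + 1, pc - half : pc + half + 1]
        rr, cc = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
        p0 = [float(sub.max() - sub.min()), 0.0, 0.0, 1.5, 1.5, float(sub.min())]
        bounds = (
            [0.0, -half, -half, 0.3, 0.3, -np.inf],
            [np.inf, half, half, float(window), float(window), np.inf],
        )
        try:
            popt, _ = curve_fit(_gauss2d, (rr, cc), sub.ravel(), p0=p0, bounds=bounds,
                                maxfev=10000)
        except (RuntimeError, ValueError):
            continue
        sigma_px = 0.5 * (popt[3] + popt[4])
        fwhms.append(FWHM_PER_SIGMA * sigma_px * pixel_size_nm)
        centers.append((pr + popt[1], pc + popt[2]))
    if not fwhms:
        raise NoQualifyingPeaksError(
            "no isolated peak passed detection and Gaussian fitting"
        )
    fwhms = np.array(fwhms)
    return PsfStats(
        fwhm_nm=fwhms,
        mean_fwhm_nm=float(fwhms.mean()),
        std_fwhm_nm=float(fwhms.std(ddof=1)) if len(fwhms) > 1 else 0.0,
        n_emitters=len(fwhms),
        details={"centers_px": centers, "background": bg, "noise_sd": noise},
    )


def resolution_improvement(
    mean_stats: PsfStats, sofi_stats: PsfStats
) -> tuple[float, float]:
    """Ratio of mean FWHMs (intensity / SOFI) with first-order error
    propagation from the two standard deviations."""
    if sofi_stats.mean_fwhm_nm == 0:
        raise ZeroDivisionError("SOFI mean FWHM is zero")
    ratio = mean_stats.mean_fwhm_nm / sofi_stats.mean_fwhm_nm
    rel = math.hypot(
        mean_stats.std_fwhm_nm / mean_stats.mean_fwhm_nm,
        sofi_stats.std_fwhm_nm / sofi_stats.mean_fwhm_nm,
    )
    return ratio, ratio * rel
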