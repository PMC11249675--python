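"""Temporal-cumulant (SOFI) analysis of fluctuation movies.

The SOFI signal at a pixel is a temporal cumulant of its intensity trace:
order 2 is the (auto)covariance of the fluctuations, order 3 the third
k-statistic.  Cumulants of independent sources add, vanish for constant
signals (which removes non-fluctuating background such as out-of-focus
light) and, for a Gaussian detection PSF, raise the PSF to the N-th power —
shrinking its width by sqrt(N).

Estimators are the unbiased k-statistics: ``sum(d^2) / (n - 1)`` for the
variance, ``sum(d_t d_{t+lag}) / (n - lag - 1)`` for lagged covariance and
``n sum(d^3) / ((n - 1)(n - 2))`` for the third cumulant, with
``d = I - mean(I)`` per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import FrameStack, ZScanSeries

__all__ = [
    "CumulantImage",
    "FluctuationReport",
    "mean_image",
    "cumulant2",
    "cumulant3",
    "sofi_zstack",
    "fluctuation_diagnostic",
]


@dataclass
class CumulantImage:
    """Per-pixel temporal cumulant of a movie (the SOFI image)."""

    order: int
    lag: int
    image: np.ndarray
    n_frames_used: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.order not in (2, 3):
            raise ValueError("only cumulant orders 2 and 3 are supported")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")


def _frames(stack: FrameStack | np.ndarray) -> np.ndarray:
    arr = stack.frames if isinstance(stack, FrameStack) else np.asarray(stack)
    if arr.ndim == 1:  # a single-pixel trace, for convenience in tests
        arr = arr[:, None, None]
    if arr.ndim != 3:
        raise ValueError("expected a (time, rows, cols) stack")
    return arr.astype(float)


def mean_image(stack: FrameStack | np.ndarray) -> np.ndarray:
    """Per-pixel arithmetic mean over time (the conventional intensity image)."""
    frames = _frames(stack)
    if len(frames) < 1:
        raise ValueError("empty stack")
    return frames.mean(axis=0)


def cumulant2(stack: FrameStack | np.ndarray, lag: int = 0) -> CumulantImage:
    """Second-order temporal cumulant image.

    ``lag=0`` is the unbiased sample variance; ``lag>0`` the sample
    autocovariance at that frame lag, which is insensitive to shot noise
    (Poisson draws are independent across frames).
    """
    frames = _frames(stack)
    n = len(frames)
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if n < lag + 2:
        raise ValueError(f"need at least lag + 2 = {lag + 2} frames, got {n}")
    d = frames - frames.mean(axis=0)
    if lag == 0:
        img = np.einsum("tij,tij->ij", d, d) / (n - 1)
    else:
        img = np.einsum("tij,tij->ij", d[:-lag], d[lag:]) / (n - lag - 1)
    meta = {"estimator": "unbiased k-statistic", "lag": lag}
    if isinstance(stack, FrameStack):
        meta.update(stack.metadata)
    return CumulantImage(2, lag, img, n, meta)


def cumulant3(stack: FrameStack | np.ndarray) -> CumulantImage:
    """Third-order temporal cumulant image (zero lag), the unbiased
    k-statistic ``k3 = n sum(d^3) / ((n - 1)(n - 2))``."""
    frames = _frames(stack)
    n = len(frames)
    if n < 3:
        raise ValueError(f"need at least 3 frames, got {n}")
    d = frames - frames.mean(axis=0)
    img = n * np.einsum("tij,tij,tij->ij", d, d, d) / ((n - 1) * (n - 2))
    meta = {"estimator": "unbiased k-statistic", "lag": 0}
    if isinstance(stack, FrameStack):
        meta.update(stack.metadata)
    return CumulantImage(3, 0, img, n, meta)


def sofi_zstack(series: ZScanSeries, order: int = 2, lag: int = 0) -> list[CumulantImage]:
    """One cumulant image per defocus position, in scan order."""
    if order == 2:
        return [cumulant2(stack, lag) for _, stack in series]
    if order == 3:
        if lag != 0:
            raise ValueError("third-order cumulant is implemented at zero lag only")
        return [cumulant3(stack) for _, stack in series]
    raise ValueError("only cumulant orders 2 and 3 are supported")


@dataclass
class FluctuationReport:
    """Outcome of the fluctuation-vs-trend diagnostic.

    ``trend_fraction`` is, per pixel, the fraction of the trace variance
    explained by a linear trend in time (R^2 of the regression of intensity
    on frame index).  The verdict aggregates over the signal-bearing pixels.
    """

    trend_fraction: np.ndarray
    pixel_mask: np.ndarray
    median_trend_fraction: float
    verdict: str


def fluctuation_diagnostic(
    stack: FrameStack | np.ndarray,
    min_mean: float | None = None,
    trend_threshold: float = 0.5,
) -> FluctuationReport:
    """Check that SOFI contrast comes from fluctuations, not slow trends.

    A movie dominated by bleaching (or other drift) produces variance that a
    linear trend explains; genuine stationary blinking does not.  Per pixel
    the fraction of variance explained by a linear fit in time is computed;
    the verdict is ``"fluctuation-dominated"`` when the median fraction over
    signal-bearing pixels is below ``trend_threshold``, else
    ``"trend-dominated"``.

    ``min_mean`` selects the pixels that enter the verdict; by default a
    robust background cut (median + 5 scaled MAD of the per-pixel means) is
    used so that empty background does not dilute the statistic.  If no
    pixel passes the cut, all pixels are used.
    """
    frames = _frames(stack)
    n = len(frames)
    if n < 10:
        raise ValueError("need at least 10 frames for a meaningful trend fit")
    t = np.arange(n, dtype=float)
    t -= t.mean()
    means = frames.mean(axis=0)
    d = frames - means
    var = np.einsum("tij,tij->ij", d, d)
    cov_t = np.einsum("t,tij->ij", t, d)
    ss_t = float(np.dot(t, t))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (cov_t**2 / ss_t) / var
    r2 = np.where(var > 0, r2, 0.0)

    if min_mean is None:
        med = float(np.median(means))
        mad = float(np.median(np.abs(means - med)))
        min_mean = med + 5.0 * 1.4826 * mad
    mask = means > min_mean
    if not mask.any():
        mask = np.ones_like(means, dtype=bool)
    median_fraction = float(np.median(r2[mask]))
    verdict = "fluctuation-dominated" if median_fraction < trend_threshold else "trend-dominated"
    return FluctuationReport(r2, mask, median_fraction, verdict)
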