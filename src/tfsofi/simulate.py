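"""Forward simulation of blinking-emitter movies and z-scans.

The generator emulates the acquisitions used to characterise temporal
focusing (TF) SOFI: for each axial (defocus) position a movie of a few
hundred 1 ms frames is recorded on a photon-number-resolving camera with a
200-count dynamic range.  Each frame is built as

    expectation = sum_i  brightness_i * state_i(t)
                  * excitation_weight(z_i - defocus)
                  * axial_attenuation(z_i - defocus)
                  * (lateral PSF integrated over the pixel area)

followed by Poisson shot noise on the photon part, camera offset, additive
Gaussian read noise, optional integer quantisation and a clamp to
``[0, max_count]``.

Coordinate conventions: emitter positions are continuous, in micrometres,
with the origin at the field centre.  Images are row-major with pixel
(0, 0) at the top-left; the centre of pixel ``(r, c)`` sits at
``(c + 0.5) * pixel_size`` horizontally and ``(r + 0.5) * pixel_size``
vertically from the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.special import erf

from .blinking import BlinkKinetics, apply_bleaching, simulate_blink_traces
from .optics import Psf3D, TFSectioningModel, tf_axial_profile

__all__ = [
    "EmitterSet",
    "CameraModel",
    "AcquisitionPlan",
    "FrameStack",
    "ZScanSeries",
    "Excitation",
    "excitation_weight",
    "render_frame",
    "simulate_movie",
    "simulate_zscan",
    "flat_layer_sample",
    "uniform_volume_sample",
]

#: Lateral rendering window half-width, in units of the PSF sigma.
RENDER_WINDOW_SIGMAS = 5.0


@dataclass(frozen=True)
class EmitterSet:
    """Point emitters: positions (um, origin at field centre) and brightness.

    ``brightness`` is the expected number of detected photons per frame when
    the emitter is ON, in focus and at the excitation maximum.
    """

    x_um: np.ndarray
    y_um: np.ndarray
    z_um: np.ndarray
    brightness: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x_um", "y_um", "z_um", "brightness"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        n = len(self.x_um)
        if any(len(getattr(self, k)) != n for k in ("y_um", "z_um", "brightness")):
            raise ValueError("emitter coordinate arrays must share one length")
        if np.any(self.brightness < 0):
            raise ValueError("brightness must be >= 0")

    def __len__(self) -> int:
        return len(self.x_um)


@dataclass(frozen=True)
class CameraModel:
    """Photon-number-resolving camera: offset, read noise, saturation clamp.

    The default 200-count ``max_count`` reflects the dynamic range of the
    photon-number-resolving readout mode the acquisitions use.
    """

    read_noise_sd: float = 0.3
    offset: float = 0.0
    max_count: float = 200.0
    quantize: bool = True
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if not 0 <= self.offset < self.max_count:
            raise ValueError("offset must satisfy 0 <= offset < max_count")

    @classmethod
    def noiseless(cls, offset: float = 0.0, max_count: float = 200.0) -> "CameraModel":
        """Ideal camera: no shot/read noise, no quantisation (clamp kept)."""
        return cls(read_noise_sd=0.0, offset=offset, max_count=max_count,
                   quantize=False, shot_noise=False)

    def apply(self, photon_expectation: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Convert expected photon images into camera counts."""
        lam = np.asarray(photon_expectation, dtype=float)
        counts = rng.poisson(lam).astype(float) if self.shot_noise else lam.copy()
        counts += self.offset
        if self.read_noise_sd > 0:
            counts += rng.normal(0.0, self.read_noise_sd, size=counts.shape)
        if self.quantize:
            counts = np.rint(counts)
        return np.clip(counts, 0.0, self.max_count)


@dataclass(frozen=True)
class AcquisitionPlan:
    """Acquisition parameters: frames per position, exposure, geometry, z plan."""

    n_frames: int = 300
    exposure_ms: float = 1.0
    frame_shape: tuple[int, int] = (64, 64)
    pixel_size_nm: float = 46.0
    z_positions_um: tuple[float, ...] = (0.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2 (temporal cumulants undefined otherwise)")
        if self.exposure_ms <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("exposure and pixel size must be > 0")
        z = np.asarray(self.z_positions_um, dtype=float)
        if z.size == 0:
            raise ValueError("z_positions_um must be nonempty")
        if z.size > 1 and not np.all(np.diff(z) > 0):
            raise ValueError("z_positions_um must be strictly increasing")
        object.__setattr__(self, "z_positions_um", tuple(float(v) for v in z))
        object.__setattr__(self, "frame_shape", (int(self.frame_shape[0]), int(self.frame_shape[1])))


@dataclass
class FrameStack:
    """A time-ordered movie of camera frames (counts)."""

    frames: np.ndarray
    pixel_size_nm: float
    exposure_ms: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, rows, cols) array")
        if len(self.frames) < 1:
            raise ValueError("stack must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ZScanSeries:
    """Movies indexed by strictly increasing defocus (um)."""

    entries: list[tuple[float, FrameStack]]

    def __post_init__(self) -> None:
        z = np.array([e[0] for e in self.entries], dtype=float)
        if z.size == 0:
            raise ValueError("z-scan series must be nonempty")
        if z.size > 1 and not np.all(np.diff(z) > 0):
            raise ValueError("defocus values must be strictly increasing")

    @property
    def z_positions_um(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries], dtype=float)

    @property
    def stacks(self) -> list[FrameStack]:
        return [e[1] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[float, FrameStack]]:
        return iter(self.entries)


@dataclass(frozen=True)
class Excitation:
    """Excitation mode: uniform wide-field or TF with an axial response model."""

    mode: str = "widefield"
    model: TFSectioningModel | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("tf", "widefield"):
            raise ValueError("mode must be 'tf' or 'widefield'")
        if self.mode == "tf" and self.model is None:
            raise ValueError("TF excitation requires a TFSectioningModel")


def excitation_weight(z_um, mode: str, model: TFSectioningModel | None = None):
    """Relative excitation strength at axial offset ``z_um`` from focus, in [0, 1].

    TF mode evaluates the axial two-photon response normalised to 1 at its
    peak (the model already describes the two-photon signal, so no further
    squaring is applied here); wide-field mode is 1 everywhere.
    """
    z = np.asarray(z_um, dtype=float)
    if mode == "widefield":
        out = np.ones_like(z)
    elif mode == "tf":
        if model is None:
            raise ValueError("TF excitation requires a TFSectioningModel")
        peak = model.offset + model.amplitude
        if peak <= 0:
            raise ValueError("TF model has zero peak response")
        out = np.asarray(tf_axial_profile(z, model)) / peak
    else:
        raise ValueError("mode must be 'tf' or 'widefield'")
    return out if out.ndim else float(out)


def _pixel_fractions_1d(
    center_from_corner_um: float, n_pixels: int, pixel_size_nm: float, sigma_nm: float
) -> tuple[int, np.ndarray]:
    """Integral of a unit-integral 1D Gaussian over each pixel in a window.

    Returns the first pixel index of the window and the per-pixel integrals;
    the window spans ``RENDER_WINDOW_SIGMAS`` sigmas, clipped to the field.
    """
    c_nm = center_from_corner_um * 1000.0
    half = RENDER_WINDOW_SIGMAS * sigma_nm
    lo = max(int(np.floor((c_nm - half) / pixel_size_nm)), 0)
    hi = min(int(np.ceil((c_nm + half) / pixel_size_nm)), n_pixels)
    if hi <= lo:
        return 0, np.empty(0)
    edges = np.arange(lo, hi + 1) * pixel_size_nm
    cdf = 0.5 * (1.0 + erf((edges - c_nm) / (sigma_nm * np.sqrt(2.0))))
    return lo, np.diff(cdf)


def _emitter_footprints(
    emitters: EmitterSet,
    defocus_um: float,
    psf: Psf3D,
    excitation: Excitation,
    frame_shape: tuple[int, int],
    pixel_size_nm: float,
) -> list[tuple[slice, slice, np.ndarray]]:
    """Per-emitter expected photon image when ON: slices into the frame plus
    the pixel-integrated lateral PSF scaled by brightness, excitation weight
    and axial detection attenuation."""
    rows, cols = frame_shape
    half_w_um = cols * pixel_size_nm / 2000.0
    half_h_um = rows * pixel_size_nm / 2000.0
    sigma = psf.sigma_lateral_nm
    out: list[tuple[slice, slice, np.ndarray]] = []
    for i in range(len(emitters)):
        dz_um = emitters.z_um[i] - defocus_um
        amp = (
            emitters.brightness[i]
            * excitation_weight(dz_um, excitation.mode, excitation.model)
            * psf.axial_attenuation(dz_um * 1000.0)
        )
        c0, fx = _pixel_fractions_1d(emitters.x_um[i] + half_w_um, cols, pixel_size_nm, sigma)
        r0, fy = _pixel_fractions_1d(emitters.y_um[i] + half_h_um, rows, pixel_size_nm, sigma)
        if fx.size == 0 or fy.size == 0 or amp == 0.0:
            out.append((slice(0, 0), slice(0, 0), np.empty((0, 0))))
            continue
        out.append((slice(r0, r0 + fy.size), slice(c0, c0 + fx.size), amp * np.outer(fy, fx)))
    return out


def render_frame(
    emitters: EmitterSet,
    states: np.ndarray,
    defocus_um: float,
    psf: Psf3D,
    excitation: Excitation,
    camera: CameraModel,
    frame_shape: tuple[int, int],
    pixel_size_nm: float,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Render one camera frame for a given per-emitter ON/OFF state vector.

    Emitters beyond the field contribute their in-field tail only; there is
    no error for out-of-field positions.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    states = np.broadcast_to(np.asarray(states, dtype=bool), (len(emitters),))
    expectation = np.zeros(frame_shape, dtype=float)
    for on, (rs, cs, fp) in zip(states, _emitter_footprints(
            emitters, defocus_um, psf, excitation, frame_shape, pixel_size_nm)):
        if on and fp.size:
            expectation[rs, cs] += fp
    return camera.apply(expectation[None], rng)[0]


def simulate_movie(
    sample: EmitterSet,
    plan: AcquisitionPlan,
    defocus_um: float,
    psf: Psf3D,
    excitation: Excitation,
    camera: CameraModel,
    kinetics: BlinkKinetics | None = None,
    bleach_rate: float = 0.0,
    seed_seq: np.random.SeedSequence | None = None,
) -> FrameStack:
    """Simulate one movie at fixed defocus: one blinking realisation per
    emitter shared by all frames, then per-frame camera noise.

    Deterministic for a fixed ``(plan.seed, defocus)``; pass ``seed_seq`` to
    override the randomness source (used by :func:`simulate_zscan`).
    """
    kinetics = kinetics if kinetics is not None else BlinkKinetics()
    if seed_seq is None:
        # same sub-seed scheme as simulate_zscan at z index 0, so a
        # single-position scan and a direct movie call agree bit for bit
        seed_seq = np.random.SeedSequence(entropy=plan.seed, spawn_key=(0,))
    blink_ss, noise_ss = seed_seq.spawn(2)
    traces = simulate_blink_traces(
        kinetics, len(sample), plan.n_frames, np.random.default_rng(blink_ss)
    )
    expectation = np.zeros((plan.n_frames,) + plan.frame_shape, dtype=float)
    footprints = _emitter_footprints(
        sample, defocus_um, psf, excitation, plan.frame_shape, plan.pixel_size_nm
    )
    for i, (rs, cs, fp) in enumerate(footprints):
        if fp.size:
            on_frames = np.nonzero(traces[i])[0]
            expectation[on_frames, rs, cs] += fp
    if bleach_rate > 0:
        expectation = apply_bleaching(expectation, bleach_rate, time_axis=0)
    frames = camera.apply(expectation, np.random.default_rng(noise_ss))
    meta = {
        "defocus_um": float(defocus_um),
        "seed": int(plan.seed),
        "n_emitters": len(sample),
        "excitation_mode": excitation.mode,
        "bleach_rate_per_frame": float(bleach_rate),
    }
    return FrameStack(frames, plan.pixel_size_nm, plan.exposure_ms, meta)


def simulate_zscan(
    sample: EmitterSet,
    plan: AcquisitionPlan,
    psf: Psf3D,
    excitation: Excitation,
    camera: CameraModel,
    kinetics: BlinkKinetics | None = None,
    bleach_rate: float = 0.0,
) -> ZScanSeries:
    """Simulate one movie per planned defocus position.

    Each z position is a separate recording, so blinking is re-drawn
    independently per z from a sub-seed derived from ``(plan.seed, z index)``.
    """
    entries = []
    for iz, z in enumerate(plan.z_positions_um):
        ss = np.random.SeedSequence(entropy=plan.seed, spawn_key=(iz,))
        stack = simulate_movie(
            sample, plan, z, psf, excitation, camera, kinetics, bleach_rate, seed_seq=ss
        )
        entries.append((float(z), stack))
    return ZScanSeries(entries)


def flat_layer_sample(
    n_emitters: int,
    field_um: float,
    z_layer_um: float = 0.0,
    brightness: float = 1000.0,
    rng: np.random.Generator | int = 0,
) -> EmitterSet:
    """Emitters uniformly random in a square lateral field, all in one plane
    (a spin-coated quantum-dot layer)."""
    if n_emitters < 1:
        raise ValueError("n_emitters must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    xy = rng.uniform(-field_um / 2.0, field_um / 2.0, size=(2, n_emitters))
    return EmitterSet(xy[0], xy[1], np.full(n_emitters, float(z_layer_um)),
                      np.full(n_emitters, float(brightness)))


def uniform_volume_sample(
    n_emitters: int,
    field_um: float,
    z_extent_um: float,
    brightness: float = 1000.0,
    rng: np.random.Generator | int = 0,
) -> EmitterSet:
    """Emitters uniformly random in a box: square lateral field, axial extent
    centred on z = 0.  Used for volumetric (multi-plane) test scenes."""
    if n_emitters < 1:
        raise ValueError("n_emitters must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    xy = rng.uniform(-field_um / 2.0, field_um / 2.0, size=(2, n_emitters))
    z = rng.uniform(-z_extent_um / 2.0, z_extent_um / 2.0, size=n_emitters)
    return EmitterSet(xy[0], xy[1], z, np.full(n_emitters, float(brightness)))
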