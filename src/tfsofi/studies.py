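"""Canonical synthetic validation studies.

Each function runs one of the package's reference measurements end to end
under fixed study conditions — the acquisition parameters the simulator is
built to emulate (300 frames x 1 ms per position, 46 nm pixels, ON fraction
0.5 blinking, photon-number-resolving camera with a 200-count clamp) — and
returns the quantity a bench characterisation would report:

* :func:`tf_fit_recovery_study` — FWHM of the TF axial response recovered
  from noisy synthetic sectioning curves (truth 2/sqrt(0.666) = 2.45 um);
* :func:`lateral_resolution_study` — mean lateral FWHM of second-order SOFI
  images of isolated blinking emitters (detection FWHM 274 nm; the
  sqrt(2)-shrunk expectation is 193.7 nm);
* :func:`axial_sectioning_study` — Gaussian FWHM of the summed second-order
  SOFI signal versus defocus for a thin emitter layer (detection axial FWHM
  680 nm; the squared profile has FWHM 480.8 nm).

All randomness derives from a single integer seed.
"""

from __future__ import annotations

import numpy as np

from .blinking import BlinkKinetics
from .optics import TFSectioningModel, make_gaussian_psf, tf_axial_profile
from .quantify import (
    PsfStats,
    SectioningCurve,
    estimate_psf_fwhm,
    fit_gaussian_sectioning,
    fit_tf_sectioning,
    summed_signal_curve,
)
from .simulate import (
    AcquisitionPlan,
    CameraModel,
    EmitterSet,
    Excitation,
    flat_layer_sample,
    simulate_movie,
    simulate_zscan,
)
from .sofi import cumulant2, mean_image, sofi_zstack

__all__ = [
    "tf_fit_recovery_study",
    "lateral_resolution_study",
    "axial_sectioning_study",
    "isolated_emitter_grid",
]

#: Lateral detection FWHM used by the resolution studies (nm).
DETECTION_LATERAL_FWHM_NM = 274.0
#: Axial detection FWHM used by the sectioning studies (nm).
DETECTION_AXIAL_FWHM_NM = 680.0
#: Expected detected photons per frame for an ON emitter at focus.
EMITTER_BRIGHTNESS = 1000.0
#: Sample pixel size (camera pixel 4.6 um / 100x magnification), nm.
PIXEL_SIZE_NM = 46.0
#: Frames recorded per axial position.
N_FRAMES = 300


def _child_seeds(seed: int, n: int, tag: int) -> list[int]:
    """Deterministic 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(tag,))
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def tf_fit_recovery_study(
    seed: int,
    n_seeds: int = 20,
    a_per_um2: float = 0.666,
    noise_fraction: float = 0.05,
    n_regions: int = 8,
) -> dict:
    """Recover the TF sectioning FWHM from noisy synthetic axial curves.

    The TF response ``1 / (1 + a z^2)`` is sampled on z in [-6, 6] um with
    0.25 um steps.  Each of ``n_regions`` regions observes the curve with
    independent multiplicative Gaussian noise (``noise_fraction`` relative
    sd); the per-z mean and across-region std form the sectioning curve,
    fitted by weighted least squares.  Repeated over ``n_seeds``
    realisations.
    """
    model = TFSectioningModel(a_per_um2=a_per_um2)
    z = np.arange(-6.0, 6.0 + 1e-9, 0.25)
    truth = tf_axial_profile(z, model)
    fwhms = []
    for s in _child_seeds(seed, n_seeds, tag=4):
        rng = np.random.default_rng(s)
        regions = truth[None, :] * (1.0 + noise_fraction * rng.standard_normal((n_regions, z.size)))
        curve = SectioningCurve(z, regions.mean(axis=0), regions.std(axis=0, ddof=0), n_regions)
        fit = fit_tf_sectioning(curve)
        if fit.success:
            fwhms.append(fit.fwhm_um)
    fwhms = np.array(fwhms)
    return {
        "fwhm_um": float(fwhms.mean()),
        "fwhm_sd_um": float(fwhms.std(ddof=1)),
        "per_seed_fwhm_um": fwhms,
        "true_fwhm_um": model.fwhm_um,
        "n_seeds": len(fwhms),
    }


def isolated_emitter_grid(
    n_emitters: int = 20,
    pitch_um: float = 2.3,
    jitter_um: float = 0.2,
    brightness: float = EMITTER_BRIGHTNESS,
    rng: np.random.Generator | int = 0,
) -> EmitterSet:
    """Well-separated in-focus emitters on a jittered rectangular grid."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nx = int(np.ceil(np.sqrt(n_emitters)))
    ny = int(np.ceil(n_emitters / nx))
    xs, ys = [], []
    for k in range(n_emitters):
        i, j = divmod(k, ny)
        xs.append((i - (nx - 1) / 2) * pitch_um + rng.uniform(-jitter_um, jitter_um))
        ys.append((j - (ny - 1) / 2) * pitch_um + rng.uniform(-jitter_um, jitter_um))
    return EmitterSet(xs, ys, np.zeros(n_emitters), np.full(n_emitters, brightness))


def lateral_resolution_study(seed: int, n_emitters: int = 20) -> dict:
    """Lateral FWHM of mean-intensity and second-order SOFI images of
    isolated blinking emitters.

    20 in-focus emitters (>= 2 um apart) blink with ON fraction 0.5 over
    300 frames at 1000 detected photons per ON frame; the camera adds shot
    noise, 0.3 counts read noise and quantisation.  PSF statistics are
    extracted from the mean image and from the lag-0 second-order cumulant
    image of the same movie.
    """
    sample = isolated_emitter_grid(n_emitters, rng=np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(5,))))
    plan = AcquisitionPlan(
        n_frames=N_FRAMES, frame_shape=(256, 256), pixel_size_nm=PIXEL_SIZE_NM, seed=seed
    )
    psf = make_gaussian_psf(DETECTION_LATERAL_FWHM_NM, DETECTION_AXIAL_FWHM_NM)
    stack = simulate_movie(
        sample, plan, 0.0, psf, Excitation("widefield"), CameraModel(), BlinkKinetics()
    )
    sofi_stats = estimate_psf_fwhm(cumulant2(stack).image, PIXEL_SIZE_NM, min_separation_nm=1000.0)
    mean_stats = estimate_psf_fwhm(mean_image(stack), PIXEL_SIZE_NM, min_separation_nm=1000.0)
    return {"sofi": sofi_stats, "intensity": mean_stats}


def _one_axial_scan(seed: int, excitation: Excitation, frame_px: int, n_emitters: int) -> float:
    z = tuple(np.round(np.arange(-1.5, 1.5 + 1e-9, 0.05), 4))
    plan = AcquisitionPlan(
        n_frames=N_FRAMES, frame_shape=(frame_px, frame_px),
        pixel_size_nm=PIXEL_SIZE_NM, z_positions_um=z, seed=seed,
    )
    field_um = frame_px * PIXEL_SIZE_NM / 1000.0
    sample = flat_layer_sample(
        n_emitters, field_um=field_um, z_layer_um=0.0, brightness=EMITTER_BRIGHTNESS,
        rng=np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(6,))),
    )
    psf = make_gaussian_psf(DETECTION_LATERAL_FWHM_NM, DETECTION_AXIAL_FWHM_NM)
    series = simulate_zscan(sample, plan, psf, excitation, CameraModel(), BlinkKinetics())
    cumulants = sofi_zstack(series, order=2, lag=0)
    curve = summed_signal_curve([c.image for c in cumulants], plan.z_positions_um, n_regions=8)
    fit = fit_gaussian_sectioning(curve, weighted=False)
    if not fit.success:
        raise RuntimeError(f"sectioning fit failed: {fit.message}")
    return fit.fwhm_um * 1000.0


def axial_sectioning_study(
    seed: int,
    n_seeds: int = 5,
    mode: str = "widefield",
    frame_px: int = 96,
    n_emitters: int = 200,
) -> dict:
    """Axial FWHM of the summed second-order SOFI signal of a thin layer.

    200 blinking emitters in one plane are scanned from -1.5 to 1.5 um in
    50 nm steps (300 frames per position); per defocus the lag-0 cumulant
    image is summed over 8 regions and the resulting curve fitted with a
    Gaussian.  ``mode="tf"`` adds the TF excitation weight with sectioning
    parameter 0.666 1/um^2 (FWHM 2.45 um) centred on the detection focus.
    """
    if mode == "tf":
        excitation = Excitation("tf", TFSectioningModel(a_per_um2=0.666))
    else:
        excitation = Excitation("widefield")
    fwhms = np.array([
        _one_axial_scan(s, excitation, frame_px, n_emitters)
        for s in _child_seeds(seed, n_seeds, tag=6)
    ])
    return {
        "fwhm_nm": float(fwhms.mean()),
        "fwhm_sd_nm": float(fwhms.std(ddof=1)) if n_seeds > 1 else 0.0,
        "per_seed_fwhm_nm": fwhms,
        "n_seeds": n_seeds,
        "mode": mode,
    }
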