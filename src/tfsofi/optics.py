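"""Optical models for temporal-focusing two-photon SOFI.

This module collects the closed-form optics used throughout the package:

* the axial two-photon response of temporal focusing (TF),
  ``F(z) = offset + amplitude / (1 + a (z - z0)^2)``, whose width parameter
  ``a`` (1/um^2) sets the optical-sectioning FWHM ``2 / sqrt(a)``;
* diffraction-limited lateral PSF width estimates;
* the ``sqrt(N)`` PSF shrink of an order-``N`` temporal cumulant (SOFI) for a
  Gaussian detection PSF;
* the 4f excitation geometry (grating imaged onto the sample by tube lens +
  objective) that sets the demagnification and illuminated field diameter;
* a separable 3D Gaussian detection PSF.

Units are explicit in field names: nanometres for wavelengths and PSF
widths, millimetres for lens geometry, micrometres for axial coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalConfig",
    "TFSectioningModel",
    "Psf3D",
    "tf_axial_profile",
    "fwhm_from_sectioning_parameter",
    "sectioning_parameter_from_fwhm",
    "lateral_fwhm_theory",
    "sofi_fwhm",
    "scale_sectioning_to_wavelength",
    "excitation_geometry",
    "make_gaussian_psf",
    "FWHM_PER_SIGMA",
]

#: Conversion between the standard deviation and the FWHM of a Gaussian,
#: 2 sqrt(2 ln 2).
FWHM_PER_SIGMA: float = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class OpticalConfig:
    """Static description of the microscope's optics.

    Defaults describe a 1030 nm femtosecond excitation source, an NA 1.4
    100x oil-immersion objective (focal length 2 mm by the 200 mm reference
    tube-length convention), a 400 mm tube lens on the excitation path and
    an 8 mm beam on the diffraction grating.
    """

    numerical_aperture: float = 1.4
    refractive_index: float = 1.518
    excitation_wavelength_nm: float = 1030.0
    emission_wavelength_nm: float = 705.0
    tube_focal_length_mm: float = 400.0
    objective_focal_length_mm: float = 2.0
    beam_diameter_at_grating_mm: float = 8.0
    pixel_size_sample_nm: float = 46.0

    def __post_init__(self) -> None:
        if not 0.0 < self.numerical_aperture <= 2.0:
            raise ValueError("numerical_aperture must be in (0, 2]")
        if self.refractive_index < 1.0:
            raise ValueError("refractive_index must be >= 1")
        if self.numerical_aperture > self.refractive_index:
            raise ValueError("numerical_aperture cannot exceed refractive_index")
        for name in (
            "excitation_wavelength_nm",
            "emission_wavelength_nm",
            "tube_focal_length_mm",
            "objective_focal_length_mm",
            "beam_diameter_at_grating_mm",
            "pixel_size_sample_nm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class TFSectioningModel:
    """Axial two-photon response of temporal focusing.

    ``F(z) = offset + amplitude / (1 + a (z - z0)^2)`` with the sectioning
    parameter ``a`` in 1/um^2 and the temporal-focus position ``z0`` in um.
    ``a = 0`` is the wide-field (no sectioning) limit.  The additive
    ``offset`` exists for fitting measured curves and defaults to 0 in the
    forward model.
    """

    a_per_um2: float
    z0_um: float = 0.0
    amplitude: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.a_per_um2 < 0:
            raise ValueError("sectioning parameter a must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def fwhm_um(self) -> float:
        """Sectioning FWHM ``2 / sqrt(a)`` (requires ``a > 0``)."""
        return fwhm_from_sectioning_parameter(self.a_per_um2)

    @classmethod
    def from_fwhm(cls, fwhm_um: float, **kwargs) -> "TFSectioningModel":
        return cls(a_per_um2=sectioning_parameter_from_fwhm(fwhm_um), **kwargs)


def tf_axial_profile(z_um, model: TFSectioningModel):
    """Evaluate the TF axial response ``F(z)`` at defocus ``z_um`` (um).

    Vectorised over ``z_um``; maximal at ``z0``, even about ``z0`` and
    monotonically decreasing in ``|z - z0|`` for ``a > 0``.
    """
    z = np.asarray(z_um, dtype=float)
    out = model.offset + model.amplitude / (1.0 + model.a_per_um2 * (z - model.z0_um) ** 2)
    return out if out.ndim else float(out)


def fwhm_from_sectioning_parameter(a_per_um2: float) -> float:
    """FWHM (um) of ``1 / (1 + a z^2)``: half maximum at ``a z^2 = 1``, so 2/sqrt(a)."""
    if a_per_um2 <= 0:
        raise ValueError("no finite FWHM: sectioning parameter a must be > 0")
    return 2.0 / math.sqrt(a_per_um2)


def sectioning_parameter_from_fwhm(fwhm_um: float) -> float:
    """Inverse of :func:`fwhm_from_sectioning_parameter`: ``a = 4 / FWHM^2``."""
    if fwhm_um <= 0:
        raise ValueError("FWHM must be > 0")
    return 4.0 / fwhm_um**2


def lateral_fwhm_theory(cfg: OpticalConfig) -> float:
    """Diffraction-limited lateral FWHM of the detection PSF, in nm.

    Uses the wide-field Gaussian approximation ``0.51 lambda_em / NA``
    (e.g. 705 nm emission at NA 1.4 gives 256.8 nm).
    """
    return 0.51 * cfg.emission_wavelength_nm / cfg.numerical_aperture


def sofi_fwhm(order: int, fwhm_nm: float) -> float:
    """PSF FWHM of the order-``N`` cumulant image: ``fwhm / sqrt(N)``.

    Valid for a Gaussian detection PSF, whose ``N``-th power is a Gaussian
    narrowed by ``sqrt(N)`` along every axis.
    """
    if order < 1:
        raise ValueError("cumulant order must be >= 1")
    if fwhm_nm <= 0:
        raise ValueError("FWHM must be > 0")
    return fwhm_nm / math.sqrt(order)


def scale_sectioning_to_wavelength(
    fwhm_nm: float, lambda_measured_nm: float, lambda_target_nm: float
) -> float:
    """Rescale a sectioning FWHM measured at one emission wavelength to another.

    Sectioning is taken as linear in emission wavelength, so the correction
    is ``fwhm * lambda_target / lambda_measured``.
    """
    if min(fwhm_nm, lambda_measured_nm, lambda_target_nm) <= 0:
        raise ValueError("all inputs must be > 0")
    return fwhm_nm * lambda_target_nm / lambda_measured_nm


def excitation_geometry(cfg: OpticalConfig) -> tuple[float, float]:
    """Demagnification of the excitation 4f telescope and field diameter.

    Returns ``(demagnification, field_diameter_um)``: the grating surface is
    imaged onto the sample with demagnification ``f_tube / f_objective``, so
    the beam diameter at the grating maps to
    ``beam_diameter / demagnification`` at the sample.
    """
    demag = cfg.tube_focal_length_mm / cfg.objective_focal_length_mm
    field_um = cfg.beam_diameter_at_grating_mm / demag * 1000.0
    return demag, field_um


@dataclass(frozen=True)
class Psf3D:
    """Separable 3D Gaussian detection PSF.

    ``normalization`` selects the value convention of :meth:`__call__`:
    ``"unit-peak"`` evaluates to 1 at the centre, ``"unit-integral"``
    integrates to 1 over all space.
    """

    lateral_fwhm_nm: float
    axial_fwhm_nm: float
    normalization: str = "unit-integral"

    def __post_init__(self) -> None:
        if self.lateral_fwhm_nm <= 0 or self.axial_fwhm_nm <= 0:
            raise ValueError("PSF FWHMs must be > 0")
        if self.normalization not in ("unit-integral", "unit-peak"):
            raise ValueError("normalization must be 'unit-integral' or 'unit-peak'")

    @property
    def sigma_lateral_nm(self) -> float:
        return self.lateral_fwhm_nm / FWHM_PER_SIGMA

    @property
    def sigma_axial_nm(self) -> float:
        return self.axial_fwhm_nm / FWHM_PER_SIGMA

    def __call__(self, x_nm, y_nm, z_nm):
        """Evaluate the PSF at offsets (nm) from its centre."""
        sx = sy = self.sigma_lateral_nm
        sz = self.sigma_axial_nm
        x = np.asarray(x_nm, dtype=float)
        y = np.asarray(y_nm, dtype=float)
        z = np.asarray(z_nm, dtype=float)
        val = np.exp(
            -(x**2) / (2 * sx**2) - y**2 / (2 * sy**2) - z**2 / (2 * sz**2)
        )
        if self.normalization == "unit-integral":
            val = val / ((2 * math.pi) ** 1.5 * sx * sy * sz)
        return val if val.ndim else float(val)

    def axial_attenuation(self, dz_nm):
        """Unit-peak axial response: fraction of in-focus signal collected
        from a point source defocused by ``dz_nm``."""
        sz = self.sigma_axial_nm
        dz = np.asarray(dz_nm, dtype=float)
        out = np.exp(-(dz**2) / (2 * sz**2))
        return out if out.ndim else float(out)


def make_gaussian_psf(
    lateral_fwhm_nm: float,
    axial_fwhm_nm: float,
    normalization: str = "unit-integral",
) -> Psf3D:
    """Construct a separable 3D Gaussian PSF from per-axis FWHMs (nm)."""
    return Psf3D(lateral_fwhm_nm, axial_fwhm_nm, normalization)
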