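"""Objective geometry, depth-dependent focal shift, and theoretical PSFs.

A high-NA oil-immersion objective imaging an aqueous specimen through a
coverglass focuses through a refractive-index mismatch (oil/glass ~1.52 vs
specimen ~1.37).  Snell's law bends the marginal ray at the glass-specimen
interface, so the apparent axial position of an object (read off the focus
knob) differs from its physical position: a positive longitudinal spherical
aberration (LS) that grows linearly with depth.  This module computes that
trigonometric chain from the objective constants, the resulting
depth-dependent shift, the Rayleigh lateral resolution in pixels, a scalar
paraxial (aberration-free) 3-D diffraction PSF for deconvolution, and the
fractional volume inflation of an ellipsoidal cell implied by the shift.

Angles follow the marginal-ray construction: ``theta`` is the half-aperture
angle of the objective (arctan of lens radius over working distance),
``theta_r`` its refraction into the specimen, and the H/L/H'/CG chain
converts the apparent coverglass-object distance into the actual one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.integrate import simpson
from scipy.special import j0

__all__ = [
    "OpticalGeometry",
    "PSFModel",
    "refraction_chain",
    "longitudinal_shift_at_depth",
    "rayleigh_radius_px",
    "theoretical_psf",
    "gaussian_psf",
    "apparent_inflation",
]


@dataclass
class OpticalGeometry:
    """Objective/immersion/specimen constants plus derived marginal-ray fields.

    Defaults reproduce a 63x/1.4 oil objective (lens radius 198.5 um,
    working distance + coverglass 310 um) imaging a specimen of refractive
    index 1.37 whose apparent distance from the coverglass is 2 um.
    Derived fields are ``None`` until :func:`refraction_chain` fills them.
    """

    r_max: float = 198.5          # objective lens radius, um
    ol_app: float = 310.0         # working distance + coverglass, um
    cg_app: float = 2.0           # apparent coverglass-object distance, um
    n_oil: float = 1.518
    n_glass: float = 1.52
    n_specimen: float = 1.37
    rounded: bool = False         # round intermediate sines to 2 decimals

    theta: Optional[float] = field(default=None)            # degrees
    theta_r: Optional[float] = field(default=None)          # degrees
    theta_prime: Optional[float] = field(default=None)      # degrees
    theta_doubleprime: Optional[float] = field(default=None)  # degrees
    h: Optional[float] = field(default=None)                # um
    h_prime: Optional[float] = field(default=None)          # um
    l: Optional[float] = field(default=None)                # um
    cg_act: Optional[float] = field(default=None)           # um
    ls: Optional[float] = field(default=None)               # um

    def numerical_aperture(self) -> float:
        """Approximate NA from the marginal-ray construction.

        Uses the double-angle form sin(2*theta) * n_oil, which treats the
        full cone captured by the lens as spanning two half-aperture
        angles; for the default constants this lands near the nominal 1.4.
        """
        theta = math.atan2(self.r_max, self.ol_app)
        return math.sin(2.0 * theta) * self.n_oil


def _maybe_round(x: float, rounded: bool, ndigits: int = 2) -> float:
    return round(x, ndigits) if rounded else x


def refraction_chain(geom: OpticalGeometry) -> OpticalGeometry:
    """Fill the derived angle/distance fields of an :class:`OpticalGeometry`.

    The chain: theta = arctan(r_max / ol_app); Snell refraction
    sin(theta_r) = sin(theta) * n_glass / n_specimen; the complementary
    angles theta' = 90 - theta and theta'' = 90 - theta_r; then
    H = cg_app / sin(theta'), L = H * sin(theta), H' = L / sin(theta_r),
    CG-ACT = H' * sin(theta''), and LS = cg_app - cg_act.

    With ``geom.rounded`` every intermediate sine is rounded to two
    decimals, reproducing hand-calculator arithmetic at two-decimal
    precision; reported angles are then rounded to two decimals as well.

    Raises
    ------
    ValueError
        If refractive indices are not > 1, cg_app <= 0, or the refracted
        sine reaches 1 (total-internal-reflection regime).
    """
    if not (geom.n_oil > 1 and geom.n_glass > 1 and geom.n_specimen > 1):
        raise ValueError("all refractive indices must exceed 1")
    if geom.cg_app <= 0:
        raise ValueError("cg_app must be positive")

    r = geom.rounded
    theta = math.degrees(math.atan2(geom.r_max, geom.ol_app))
    sin_theta = _maybe_round(math.sin(math.radians(theta)), r)

    ratio = geom.n_glass / geom.n_specimen
    sin_theta_r = sin_theta * ratio
    if sin_theta_r >= 1.0:
        raise ValueError(
            "sin(theta) * n_glass/n_specimen >= 1: total internal reflection"
        )
    theta_r = math.degrees(math.asin(sin_theta_r))

    theta_prime = 90.0 - (_maybe_round(theta, r) if r else theta)
    theta_doubleprime = 90.0 - (_maybe_round(theta_r, r) if r else theta_r)

    sin_theta_prime = _maybe_round(math.sin(math.radians(theta_prime)), r)
    h = geom.cg_app / sin_theta_prime
    l = h * sin_theta
    sin_tr = _maybe_round(math.sin(math.radians(theta_r)), r)
    h_prime = l / sin_tr
    sin_tdp = _maybe_round(math.sin(math.radians(theta_doubleprime)), r)
    cg_act = h_prime * sin_tdp
    ls = geom.cg_app - cg_act

    return replace(
        geom,
        theta=_maybe_round(theta, r),
        theta_r=_maybe_round(theta_r, r),
        theta_prime=_maybe_round(theta_prime, r),
        theta_doubleprime=_maybe_round(theta_doubleprime, r),
        h=h,
        h_prime=h_prime,
        l=l,
        cg_act=cg_act,
        ls=ls,
    )


def longitudinal_shift_at_depth(geom: OpticalGeometry, depth: float) -> float:
    """Longitudinal shift (um) at a given apparent depth below the coverglass.

    The shift scales linearly with depth: ls * depth / cg_app.  ``geom``
    must have been through :func:`refraction_chain`.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if geom.ls is None:
        geom = refraction_chain(geom)
    return geom.ls * depth / geom.cg_app


def rayleigh_radius_px(
    wavelength_nm: float,
    na: float,
    pixel_nm: float,
    coefficient: float = 0.6,
) -> float:
    """Rayleigh lateral resolution radius in pixels: coefficient * lambda / NA / pixel."""
    if wavelength_nm <= 0 or na <= 0 or pixel_nm <= 0:
        raise ValueError("wavelength, NA and pixel size must be positive")
    return coefficient * wavelength_nm / na / pixel_nm


@dataclass
class PSFModel:
    """Parameters of a scalar paraxial diffraction PSF.

    emission_wavelength in nm; voxel_size is (z, y, x) in um; the immersion
    index sets the axial defocus scaling.  The kernel produced from this
    model is radially symmetric laterally, mirror-symmetric axially, and
    normalised to unit sum.
    """

    emission_wavelength: float = 510.0
    numerical_aperture: float = 1.4
    voxel_size: tuple[float, float, float] = (0.130, 0.0425, 0.0425)
    n_immersion: float = 1.518

    def rayleigh_radius_px(self, coefficient: float = 0.6) -> float:
        pixel_nm = self.voxel_size[2] * 1000.0
        return rayleigh_radius_px(
            self.emission_wavelength, self.numerical_aperture, pixel_nm, coefficient
        )


def theoretical_psf(
    model: PSFModel, shape: tuple[int, int, int] = (13, 33, 33)
) -> np.ndarray:
    """Scalar paraxial 3-D diffraction kernel (no aberration terms).

    Intensity at optical coordinates (v, u) is the modulus-squared of the
    pupil integral  int_0^1 J0(v*rho) exp(i*u*rho^2/2) rho drho  with
    v = k*NA*r and u = k*NA^2*z/n, evaluated at voxel centres.  In focus
    this is the Airy pattern (first zero at 0.61 lambda/NA); out of focus
    it is the symmetric paraxial defocus pattern.  The kernel is normalised
    to unit sum; its centre voxel is the global maximum.

    Parameters
    ----------
    shape : (nz, ny, nx), all odd so the focal point sits on a voxel centre.
    """
    nz, ny, nx = shape
    if any(s % 2 == 0 for s in shape):
        raise ValueError("PSF shape must be odd along every axis")

    lam_um = model.emission_wavelength / 1000.0
    na = model.numerical_aperture
    dz, dy, dx = model.voxel_size
    k = 2.0 * math.pi / lam_um

    first_zero_um = 0.61 * lam_um / na
    if (nx // 2) * dx < first_zero_um or (ny // 2) * dy < first_zero_um:
        warnings.warn(
            "PSF window smaller than the first Airy minimum; kernel is truncated",
            stacklevel=2,
        )

    z = (np.arange(nz) - nz // 2) * dz
    y = (np.arange(ny) - ny // 2) * dy
    x = (np.arange(nx) - nx // 2) * dx
    r = np.hypot(y[:, None], x[None, :])          # (ny, nx)

    v = k * na * r                                 # lateral optical coords
    u = k * na**2 * z / model.n_immersion          # axial optical coords

    rho = np.linspace(0.0, 1.0, 101)
    # integrand over (nz, ny*nx, nrho); evaluated lazily per z-plane to
    # bound memory
    bessel = j0(v.ravel()[:, None] * rho[None, :]) * rho[None, :]
    kernel = np.empty((nz, ny, nx))
    for iz in range(nz):
        phase = np.exp(1j * u[iz] * rho**2 / 2.0)
        amp = simpson(bessel * phase[None, :], x=rho, axis=1)
        kernel[iz] = np.abs(amp.reshape(ny, nx)) ** 2

    kernel /= kernel.sum()
    return kernel


def gaussian_psf(
    fwhm_lateral_um: float = 0.14,
    fwhm_axial_um: float = 0.35,
    voxel_size: tuple[float, float, float] = (0.130, 0.0425, 0.0425),
    shape: tuple[int, int, int] = (9, 17, 17),
) -> np.ndarray:
    """Compact Gaussian blur kernel modelling a processed-acquisition PSF.

    Pixel-reassignment/deconvolution-style detection chains deliver an
    effective PSF well approximated by a Gaussian with the instrument's
    advertised resolution (defaults: 140 nm lateral, 350 nm axial FWHM).
    Used to model the blur already present in acquired stacks, as opposed
    to the diffraction kernel of :func:`theoretical_psf` used for
    deconvolution.  Unit sum, centred, mirror-symmetric.
    """
    nz, ny, nx = shape
    if any(s % 2 == 0 for s in shape):
        raise ValueError("PSF shape must be odd along every axis")
    dz, dy, dx = voxel_size
    sz = fwhm_axial_um / 2.354820045
    sl = fwhm_lateral_um / 2.354820045
    z = (np.arange(nz) - nz // 2) * dz
    y = (np.arange(ny) - ny // 2) * dy
    x = (np.arange(nx) - nx // 2) * dx
    kernel = (
        np.exp(-0.5 * (z[:, None, None] / sz) ** 2)
        * np.exp(-0.5 * (y[None, :, None] / sl) ** 2)
        * np.exp(-0.5 * (x[None, None, :] / sl) ** 2)
    )
    return kernel / kernel.sum()


def apparent_inflation(
    thickness_apparent: float,
    geom: OpticalGeometry,
    depth_top: Optional[float] = None,
    depth_bottom: Optional[float] = None,
) -> float:
    """Fractional apparent volume inflation of an ellipsoidal cell.

    The depth-dependent longitudinal shift stretches the apparent axial
    extent of the cell: the top focal plane (shallow) is shifted less than
    the bottom one (deep), so the apparent thickness exceeds the actual
    thickness by the LS span across the cell.  Modelling the cell as an
    ellipsoid whose axial semi-axis alone is rescaled, the fractional
    volume inflation equals thickness_apparent / thickness_actual - 1.

    By default the cell is centred at the apparent distance ``geom.cg_app``
    so the focal planes span cg_app +/- thickness/2.
    """
    if thickness_apparent <= 0:
        raise ValueError("apparent thickness must be positive")
    if geom.ls is None:
        geom = refraction_chain(geom)
    if depth_top is None:
        depth_top = geom.cg_app - thickness_apparent / 2.0
    if depth_bottom is None:
        depth_bottom = geom.cg_app + thickness_apparent / 2.0
    ls_span = longitudinal_shift_at_depth(geom, depth_bottom) - longitudinal_shift_at_depth(
        geom, max(depth_top, 0.0)
    )
    if ls_span >= thickness_apparent:
        raise ValueError("LS span exceeds apparent thickness; geometry inconsistent")
    actual = thickness_apparent - ls_span
    return thickness_apparent / actual - 1.0
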