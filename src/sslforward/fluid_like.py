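"""Distorted-wave Born approximation (DWBA) models for fluid-like bodies.

Weakly scattering zooplankton (euphausiids, decapod shrimp, copepods) and
fish without swimbladders are modelled as fluid bodies whose density and
sound-speed contrasts with seawater (g, h) are close to 1. The DWBA
expresses the backscattering amplitude as a line integral along the body
axis of a deformed cylinder:

    f_bs = (k1 / 4) * integral  Gamma * a(s)
           * 2 * J1(2 k2 a(s) cos(beta)) / (2 k2 a(s) cos(beta)) * 2 k2 a(s)
           ... equivalently a(s) * J1(x)/cos(beta), x = 2 k2 a(s) cos(beta)

with material contrast Gamma = (1 - g h^2)/(g h^2) - (g - 1)/g, interior
wavenumber k2 = k1/h, local radius a(s), and beta the angle between the
incident direction and the cross-sectional plane of the axis at s.

Two body shapes are supported:

* ``prolate_spheroid`` — straight axis, elliptical taper
  a(s) = a0 sqrt(1 - (2 s / L)^2); used for copepods.
* ``bent_cylinder`` — axis bent on a circular arc of radius rho_c = c_r * L
  (default c_r = 3) with a smooth taper a(s) = a0 sqrt(1 - (2 s / L)^n)
  of order n = 10; used for shrimp-like bodies and bladderless fish.

Backscatter is averaged in the linear (sigma_bs) domain over a normal
distribution of body tilt angles, the angle of the body axis above the
horizontal plane for a vertically looking echosounder. The average uses
deterministic Gauss-Legendre quadrature over mean +/- 3 SD weighted by the
normal density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre
from scipy.special import j1

from .medium import Medium, wavenumber
from .spectra import TSSpectrum, linear_to_db, sentinel_spectrum

_SHAPES = ("bent_cylinder", "prolate_spheroid")


@dataclass(frozen=True)
class FluidLikeParams:
    """Material and shape parameters of a fluid-like scatterer population.

    ``length_to_radius_ratio`` is L/a, body length over the radius of the
    mid-body circular cross-section (twice the commonly tabulated
    length-to-width ratio L/2a). Orientation is the body tilt from the
    horizontal in degrees; the incident wave travels vertically.
    """

    g: float
    h: float
    length_to_radius_ratio: float
    orientation_mean_deg: float
    orientation_sd_deg: float
    shape: str
    curvature_ratio: float = 3.0  # rho_c = curvature_ratio * L (bent cylinder)
    taper_order: int = 10  # bent-cylinder taper exponent

    def __post_init__(self) -> None:
        if self.g <= 0 or self.h <= 0:
            raise ValueError("contrasts g and h must be positive")
        if self.length_to_radius_ratio <= 0:
            raise ValueError("length_to_radius_ratio must be positive")
        if self.orientation_sd_deg < 0:
            raise ValueError("orientation SD must be >= 0")
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}, got {self.shape!r}")


def material_contrast(g: float, h: float) -> float:
    """DWBA contrast term Gamma = gamma_kappa - gamma_rho."""
    gamma_kappa = (1.0 - g * h * h) / (g * h * h)
    gamma_rho = (g - 1.0) / g
    return gamma_kappa - gamma_rho


def orientation_nodes(mean_deg: float, sd_deg: float, n_nodes: int = 61):
    """Gauss-Legendre nodes/weights for the tilt-angle average.

    Returns angles (deg) and normalized weights under N(mean, sd). A zero
    SD collapses to the single angle at the mean.
    """
    if sd_deg == 0:
        return np.array([mean_deg]), np.array([1.0])
    x, w = legendre.leggauss(n_nodes)
    lo, hi = mean_deg - 3.0 * sd_deg, mean_deg + 3.0 * sd_deg
    theta = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    pdf = np.exp(-0.5 * ((theta - mean_deg) / sd_deg) ** 2)
    weights = w * pdf
    return theta, weights / weights.sum()


def _axis_geometry(shape: str, length_m: float, s: np.ndarray,
                   curvature_ratio: float):
    """Axis positions (x, z) and tangents for arclength samples ``s``."""
    if shape == "prolate_spheroid":
        x, z = s, np.zeros_like(s)
        tx, tz = np.ones_like(s), np.zeros_like(s)
    else:  # bent cylinder: circular arc in the x-z plane
        rho_c = curvature_ratio * length_m
        alpha = s / rho_c
        x = rho_c * np.sin(alpha)
        z = rho_c * (1.0 - np.cos(alpha))
        tx, tz = np.cos(alpha), np.sin(alpha)
    return x, z, tx, tz


def _taper(shape: str, a0: float, s: np.ndarray, length_m: float,
           taper_order: int) -> np.ndarray:
    u = np.clip(2.0 * s / length_m, -1.0, 1.0)
    if shape == "prolate_spheroid":
        prof = 1.0 - u * u
    else:
        prof = 1.0 - np.abs(u) ** taper_order
    return a0 * np.sqrt(np.clip(prof, 0.0, None))


def _j1_over_x(x: np.ndarray) -> np.ndarray:
    """J1(x)/x with its analytic limit 1/2 at x = 0."""
    out = np.full(x.shape, 0.5)
    nz = np.abs(x) > 1e-12
    out[nz] = j1(x[nz]) / x[nz]
    return out


def dwba_amplitude(length_m: float, a0_m: float, tilt_deg: float,
                   params: FluidLikeParams, k1: np.ndarray,
                   n_axis: int | None = None) -> np.ndarray:
    """Complex backscattering amplitude f_bs (m) per frequency.

    ``k1`` is the array of medium wavenumbers (1/m); the interior
    wavenumber is k1/h. Integration uses composite Simpson on an odd
    number of axis nodes chosen from the maximum phase k2*L.
    """
    k1 = np.atleast_1d(np.asarray(k1, dtype=float))
    k2 = k1 / params.h
    if n_axis is None:
        n_axis = max(129, int(10.0 * np.max(k2) * length_m))
    if n_axis % 2 == 0:
        n_axis += 1
    s = np.linspace(-length_m / 2.0, length_m / 2.0, n_axis)
    x, z, tx, tz = _axis_geometry(params.shape, length_m, s,
                                  params.curvature_ratio)
    a_s = _taper(params.shape, a0_m, s, length_m, params.taper_order)

    # incident unit vector in the body frame: tilt above horizontal, the
    # wave travels vertically, so d = (sin(theta), cos(theta)) in (x, z)
    th = np.deg2rad(tilt_deg)
    dx, dz = np.sin(th), np.cos(th)
    proj = dx * x + dz * z          # d . r(s)
    cos_beta_sq = 1.0 - (dx * tx + dz * tz) ** 2
    cos_beta = np.sqrt(np.clip(cos_beta_sq, 0.0, 1.0))

    gamma = material_contrast(params.g, params.h)
    # integrand over (freq, s)
    arg = 2.0 * k2[:, None] * a_s[None, :] * cos_beta[None, :]
    bessel_term = 2.0 * k2[:, None] * a_s[None, :] * _j1_over_x(arg)
    phase = np.exp(2.0j * k2[:, None] * proj[None, :])
    integrand = gamma * a_s[None, :] * bessel_term * phase

    integral = _simpson(integrand, s)
    return (k1 / 4.0) * integral


def _simpson(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    h = x[1] - x[0]
    w = np.ones(x.shape)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return (h / 3.0) * (y * w[None, :]).sum(axis=1)


def ts_fluid_like(length_mm: float, params: FluidLikeParams, medium: Medium,
                  frequencies_khz, n_axis: int | None = None,
                  n_orientations: int = 61) -> TSSpectrum:
    """Orientation-averaged DWBA target strength spectrum.

    The backscattering cross-section sigma_bs = |f_bs|^2 is averaged in
    linear scale over the tilt distribution N(mean, SD); TS is
    10 log10(sigma_bs) in dB re 1 m^2. A body with no acoustic contrast
    (g = h = 1) returns the zero-backscatter sentinel spectrum.
    """
    if length_mm <= 0:
        raise ValueError("length must be positive (mm)")
    freqs = np.asarray(frequencies_khz, dtype=float)
    if params.g == 1.0 and params.h == 1.0:
        return sentinel_spectrum(freqs, TSSpectrum)
    length_m = length_mm * 1e-3
    a0_m = length_m / params.length_to_radius_ratio
    k1 = wavenumber(freqs, medium)

    angles, weights = orientation_nodes(params.orientation_mean_deg,
                                        params.orientation_sd_deg,
                                        n_orientations)
    sigma = np.zeros(freqs.shape)
    for theta, w in zip(angles, weights):
        f_bs = dwba_amplitude(length_m, a0_m, theta, params, k1, n_axis)
        sigma += w * np.abs(f_bs) ** 2
    return TSSpectrum(freqs, linear_to_db(sigma))
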