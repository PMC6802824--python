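"""Damped resonant scattering by gas-bearing organisms.

Siphonophore pneumatophores and fish swimbladders are modelled as gas-filled
prolate spheroids in the Rayleigh regime. The model combines:

* the Minnaert monopole resonance of the equal-volume sphere, with a
  surface-tension (tissue tension) correction to the stiffness:

      omega_0^2 = [3 gamma (P + 2 tau / r) - 2 tau / r] / (rho r^2)

  where r = (a^2 b)^(1/3) is the equal-volume radius, P the ambient
  hydrostatic pressure and tau the surface tension at the gas/tissue
  interface;

* a prolate-shape correction from the electrostatic-capacitance analogy
  for a pulsating non-spherical bubble: the resonance frequency scales as
  sqrt(C / r) with C the capacitance of the spheroid
  (C = 2 b e / ln((1+e)/(1-e)), e the eccentricity), so an elongated
  inclusion of the same volume resonates slightly above the sphere;

* frequency-dependent total damping

      delta(f) = k r  (radiation)
               + 4 eta / (rho omega r^2)  (viscosity of surrounding tissue)
               + thermal damping from the complex polytropic factor of gas
                 heat conduction (Devin-style), evaluated per frequency.

The backscattering cross-section is the classical damped-resonance form

    sigma_bs(f) = r^2 / ( ((f_R / f)^2 - 1)^2 + delta(f)^2 ).

The model is a Rayleigh-regime approximation, valid for k b < 0.1; outside
that range the spectrum is still computed but flagged in the validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .medium import Medium, wavenumber
from .spectra import TSSpectrum, linear_to_db

# Gas (air) properties used for thermal damping
AIR_MOLAR_GAS_CONSTANT = 287.05  # J/(kg K), specific gas constant of air
AIR_THERMAL_CONDUCTIVITY = 0.025  # W/(m K)
AIR_CP = 1005.0  # J/(kg K)


@dataclass(frozen=True)
class GasBearingParams:
    """Physical parameters of a gas inclusion and its surrounding tissue.

    ``length_to_width_ratio`` is L/2a = b/a of the prolate inclusion
    (>= 1); ``viscosity`` (Pa s) and ``surface_tension`` (N/m) describe the
    enclosing tissue; ``gas_gamma`` is the heat-capacity ratio of the gas.
    """

    length_to_width_ratio: float
    viscosity: float
    surface_tension: float
    gas_gamma: float = 1.4

    def __post_init__(self) -> None:
        if self.length_to_width_ratio < 1.0:
            raise ValueError("length_to_width_ratio must be >= 1")
        if self.viscosity < 0 or self.surface_tension < 0:
            raise ValueError("viscosity and surface tension must be >= 0")
        if self.gas_gamma <= 1.0:
            raise ValueError("gas_gamma must exceed 1")


def semi_axes_m(gas_length_mm: float, ratio: float) -> tuple[float, float]:
    """Semi-minor and semi-major axes (m) of the inclusion: b = L/2, a = b/ratio."""
    if gas_length_mm <= 0:
        raise ValueError("gas inclusion length must be positive (mm)")
    b = gas_length_mm * 1e-3 / 2.0
    return b / ratio, b


def prolate_shape_factor(ratio: float) -> float:
    """Resonance-frequency multiplier sqrt(C / r_eq) for aspect ratio b/a.

    Equals 1 in the sphere limit and grows slowly with elongation
    (about +3% at b/a = 2.35).
    """
    if ratio < 1.0:
        raise ValueError("aspect ratio must be >= 1")
    if ratio - 1.0 < 1e-9:
        return 1.0
    e = np.sqrt(1.0 - 1.0 / ratio**2)
    capacitance_over_b = 2.0 * e / np.log((1.0 + e) / (1.0 - e))
    r_eq_over_b = ratio ** (-2.0 / 3.0)
    return float(np.sqrt(capacitance_over_b / r_eq_over_b))


def minnaert_frequency(radius_m: float, medium: Medium, gamma: float = 1.4,
                       surface_tension: float = 0.0) -> float:
    """Monopole resonance (Hz) of a gas sphere, with tension correction."""
    P = medium.ambient_pressure
    r = radius_m
    stiffness = 3.0 * gamma * (P + 2.0 * surface_tension / r) \
        - 2.0 * surface_tension / r
    return float(np.sqrt(stiffness / (medium.density * r * r)) / (2.0 * np.pi))


def _thermal_polytropic(f_hz: np.ndarray, radius_m: float, gamma: float,
                        pressure_pa: float, temperature_k: float) -> np.ndarray:
    """Complex factor Phi(f): Re(Phi)/3 is the effective polytropic index,
    Im/Re the thermal loss tangent. Limits: Phi -> 3 (isothermal, f -> 0)
    and Phi -> 3 gamma (adiabatic, f -> inf)."""
    omega = 2.0 * np.pi * f_hz
    rho_g = pressure_pa / (AIR_MOLAR_GAS_CONSTANT * temperature_k)
    d_gas = AIR_THERMAL_CONDUCTIVITY / (rho_g * AIR_CP)
    lam = np.sqrt(1j * omega * radius_m**2 / d_gas)
    # coth(lam) ~ 1 for large |Re lam|; series for small |lam|
    small = np.abs(lam) < 1e-3
    big = np.real(lam) > 25.0
    coth = np.empty_like(lam)
    mid = ~(small | big)
    coth[mid] = np.cosh(lam[mid]) / np.sinh(lam[mid])
    coth[big] = 1.0
    coth[small] = 1.0 / lam[small] + lam[small] / 3.0
    return 3.0 * gamma / (1.0 + (3.0 * (gamma - 1.0) / lam**2)
                          * (lam * coth - 1.0))


def ts_gas_bearing(gas_length_mm: float, params: GasBearingParams,
                   medium: Medium, frequencies_khz) -> TSSpectrum:
    """Target strength spectrum of a gas-filled prolate spheroid.

    ``gas_length_mm`` is the major-axis length of the gas inclusion
    (pneumatophore or swimbladder). Frequencies where k b >= 0.1 are
    outside the Rayleigh validity of the model and are flagged False in
    the validity mask (values are still computed).
    """
    freqs = np.asarray(frequencies_khz, dtype=float)
    a, b = semi_axes_m(gas_length_mm, params.length_to_width_ratio)
    r_eq = (a * a * b) ** (1.0 / 3.0)
    shape = prolate_shape_factor(params.length_to_width_ratio)
    f_res = shape * minnaert_frequency(r_eq, medium, params.gas_gamma,
                                       params.surface_tension)

    f_hz = freqs * 1e3
    omega = 2.0 * np.pi * f_hz
    k = wavenumber(freqs, medium)

    p_inside = medium.ambient_pressure + 2.0 * params.surface_tension / r_eq
    phi = _thermal_polytropic(f_hz, r_eq, params.gas_gamma, p_inside,
                              medium.temperature)
    ratio2 = (f_res / f_hz) ** 2
    delta = (
        k * r_eq
        + 4.0 * params.viscosity / (medium.density * omega * r_eq**2)
        + ratio2 * np.imag(phi) / np.real(phi)
    )
    # guard the exact-resonance, zero-damping degenerate case
    delta = np.maximum(delta, 1e-12)
    sigma = r_eq**2 / ((ratio2 - 1.0) ** 2 + delta**2)
    mask = k * b < 0.1
    return TSSpectrum(freqs, linear_to_db(sigma), mask)
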