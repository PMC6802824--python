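"""Independent oracle implementations used only by the test suite.

These deliberately re-derive results through different code paths than the
package: adaptive quadrature instead of fixed-node Simpson for the DWBA
line integral, and a scalar, formula-by-formula damped resonant sphere.
They share only the physical definitions, not the implementation.
"""

from __future__ import annotations

import cmath
import math

import numpy as np
from scipy.integrate import quad
from scipy.special import jv


def dwba_quad_amplitude(length_m: float, a0_m: float, tilt_deg: float,
                        g: float, h: float, shape: str, k1: float,
                        curvature_ratio: float = 3.0,
                        taper_order: int = 10) -> complex:
    """Backscattering amplitude of a deformed fluid cylinder by adaptive
    quadrature over the body axis (independent of the package's Simpson
    integration)."""
    k2 = k1 / h
    gamma = (1.0 - g * h * h) / (g * h * h) - (g - 1.0) / g
    th = math.radians(tilt_deg)
    dx, dz = math.sin(th), math.cos(th)

    def point(s: float):
        if shape == "prolate_spheroid":
            x, z, tx, tz = s, 0.0, 1.0, 0.0
            prof = 1.0 - (2.0 * s / length_m) ** 2
        elif shape == "bent_cylinder":
            rc = curvature_ratio * length_m
            al = s / rc
            x, z = rc * math.sin(al), rc * (1.0 - math.cos(al))
            tx, tz = math.cos(al), math.sin(al)
            prof = 1.0 - abs(2.0 * s / length_m) ** taper_order
        else:
            raise ValueError(shape)
        radius = a0_m * math.sqrt(max(prof, 0.0))
        return x, z, tx, tz, radius

    def integrand(s: float) -> complex:
        x, z, tx, tz, radius = point(s)
        cosb2 = 1.0 - (dx * tx + dz * tz) ** 2
        cosb = math.sqrt(max(cosb2, 0.0))
        arg = 2.0 * k2 * radius * cosb
        if arg < 1e-12:
            bess = k2 * radius  # limit of J1(x)/cos(beta) as cos(beta)->0
        else:
            bess = jv(1, arg) / cosb
        return gamma * radius * bess * cmath.exp(2j * k2 * (dx * x + dz * z))

    half = length_m / 2.0
    re = quad(lambda s: integrand(s).real, -half, half, limit=400)[0]
    im = quad(lambda s: integrand(s).imag, -half, half, limit=400)[0]
    return (k1 / 4.0) * complex(re, im)


def dwba_quad_sigma_averaged(length_m, a0_m, g, h, shape, k1,
                             mean_deg, sd_deg, n_nodes=61,
                             curvature_ratio=3.0, taper_order=10) -> float:
    """Orientation-averaged sigma_bs using the quadrature amplitude."""
    from numpy.polynomial import legendre
    if sd_deg == 0:
        f = dwba_quad_amplitude(length_m, a0_m, mean_deg, g, h, shape, k1,
                                curvature_ratio, taper_order)
        return abs(f) ** 2
    x, w = legendre.leggauss(n_nodes)
    theta = mean_deg + 3.0 * sd_deg * x
    pdf = np.exp(-0.5 * ((theta - mean_deg) / sd_deg) ** 2)
    weights = w * pdf
    weights = weights / weights.sum()
    total = 0.0
    for t, wt in zip(theta, weights):
        f = dwba_quad_amplitude(length_m, a0_m, float(t), g, h, shape, k1,
                                curvature_ratio, taper_order)
        total += wt * abs(f) ** 2
    return total


# ----------------------------------------------------------------------
def damped_minnaert_sigma(f_hz: float, radius_m: float, depth_m: float,
                          viscosity: float, surface_tension: float,
                          gamma: float = 1.4, rho: float = 1026.0,
                          c: float = 1500.0,
                          temperature_k: float = 283.15) -> float:
    """sigma_bs of a damped resonant gas *sphere*, scalar transcription.

    Resonance: omega0^2 = [3 gamma (P + 2 tau/r) - 2 tau/r] / (rho r^2).
    Damping: radiation k r, viscous 4 eta / (rho omega r^2), and the
    thermal loss tangent of gas heat conduction scaled by (f0/f)^2.
    """
    P0 = 101325.0
    P = P0 * (1.0 + depth_m / 10.0)
    r = radius_m
    tau = surface_tension
    stiffness = 3.0 * gamma * (P + 2.0 * tau / r) - 2.0 * tau / r
    f0 = math.sqrt(stiffness / (rho * r * r)) / (2.0 * math.pi)

    omega = 2.0 * math.pi * f_hz
    k = omega / c
    # thermal: Devin-style complex polytropic factor
    p_in = P + 2.0 * tau / r
    rho_gas = p_in / (287.05 * temperature_k)
    d_gas = 0.025 / (rho_gas * 1005.0)
    lam = cmath.sqrt(1j * omega * r * r / d_gas)
    if lam.real > 25.0:
        coth = 1.0
    elif abs(lam) < 1e-3:
        coth = 1.0 / lam + lam / 3.0
    else:
        coth = cmath.cosh(lam) / cmath.sinh(lam)
    phi = 3.0 * gamma / (1.0 + (3.0 * (gamma - 1.0) / (lam * lam))
                         * (lam * coth - 1.0))
    beta = (f0 / f_hz) ** 2
    delta = (k * r + 4.0 * viscosity / (rho * omega * r * r)
             + beta * phi.imag / phi.real)
    delta = max(delta, 1e-12)
    return r * r / ((beta - 1.0) ** 2 + delta * delta)
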