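"""High-pass dense-fluid sphere model for elastic-shelled organisms.

Thecosome pteropods carry a hard aragonite shell: at low frequency they
scatter in the Rayleigh regime (sigma_bs rising as (ka)^4) while at high
frequency the cross-section saturates at the geometric-optics limit of a
dense sphere, sigma_bs = a^2 R^2 / 4, with R an empirically derived
reflection coefficient. The high-pass form interpolates smoothly between
the two regimes:

    sigma_bs = a^2 (ka)^4 alpha^2 / (1 + 4 (ka)^4 alpha^2 / R^2)

where alpha is the Rayleigh coefficient of a dense fluid sphere,

    alpha = (1 - g h^2) / (3 g h^2) + (1 - g) / (1 + 2 g),

evaluated at aragonite-like material contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .medium import Medium, wavenumber
from .spectra import TSSpectrum, linear_to_db, sentinel_spectrum


@dataclass(frozen=True)
class ElasticShellParams:
    """Parameters of the high-pass dense-fluid sphere model.

    ``reflection_coefficient`` R in [0, 1] sets the geometric plateau;
    ``shell_g``/``shell_h`` are the density and sound-speed contrasts of
    the shell material (aragonite defaults) controlling the Rayleigh
    coefficient.
    """

    reflection_coefficient: float = 0.5
    shell_g: float = 2.62
    shell_h: float = 2.32

    def __post_init__(self) -> None:
        if not 0.0 <= self.reflection_coefficient <= 1.0:
            raise ValueError("reflection coefficient must lie in [0, 1]")
        if self.shell_g <= 0 or self.shell_h <= 0:
            raise ValueError("shell contrasts must be positive")


def rayleigh_coefficient(g: float, h: float) -> float:
    """Dense fluid sphere Rayleigh coefficient alpha."""
    return (1.0 - g * h * h) / (3.0 * g * h * h) + (1.0 - g) / (1.0 + 2.0 * g)


def ts_elastic_shell(equivalent_radius_mm: float, params: ElasticShellParams,
                     medium: Medium, frequencies_khz) -> TSSpectrum:
    """Target strength spectrum of a shelled organism.

    ``equivalent_radius_mm`` is the radius of a disc with the same area as
    the organism's silhouette. R = 0 yields the zero-backscatter sentinel.
    The cross-section is monotone non-decreasing in frequency.
    """
    if equivalent_radius_mm <= 0:
        raise ValueError("equivalent radius must be positive (mm)")
    freqs = np.asarray(frequencies_khz, dtype=float)
    R = params.reflection_coefficient
    if R == 0.0:
        return sentinel_spectrum(freqs, TSSpectrum)
    a = equivalent_radius_mm * 1e-3
    ka = wavenumber(freqs, medium) * a
    alpha2 = rayleigh_coefficient(params.shell_g, params.shell_h) ** 2
    ka4 = ka ** 4
    sigma = a * a * ka4 * alpha2 / (1.0 + 4.0 * ka4 * alpha2 / (R * R))
    return TSSpectrum(freqs, linear_to_db(sigma))
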