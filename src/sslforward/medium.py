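"""Acoustic properties of the seawater medium.

Default sound speed and density are typical continental-shelf values;
hydrographic profiles can override them through the run configuration.
Ambient pressure follows the hydrostatic rule-of-thumb P(z) = P0 * (1 + z/10),
i.e. one extra atmosphere per 10 m of depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ATMOSPHERE_PA = 101_325.0

#: Default water temperature (K) used for gas properties inside inclusions.
DEFAULT_TEMPERATURE_K = 283.15


@dataclass(frozen=True)
class Medium:
    """Seawater surrounding the scatterers.

    Parameters
    ----------
    sound_speed : float
        Sound speed c in m/s. Must be positive.
    density : float
        Density rho in kg/m^3. Must be positive.
    depth : float
        Depth z in metres (>= 0); sets the ambient pressure felt by
        gas inclusions.
    temperature : float
        Water temperature in kelvin, used for the gas thermodynamics of
        gas-bearing scatterers.
    """

    sound_speed: float = 1500.0
    density: float = 1026.0
    depth: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.sound_speed <= 0:
            raise ValueError(f"sound_speed must be > 0, got {self.sound_speed}")
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")

    @property
    def ambient_pressure(self) -> float:
        """Hydrostatic ambient pressure in Pa: P0 * (1 + z / 10)."""
        return ATMOSPHERE_PA * (1.0 + self.depth / 10.0)


def wavenumber(frequency_khz, medium: Medium):
    """Acoustic wavenumber k = 2 pi f / c in 1/m.

    ``frequency_khz`` may be a scalar or array of frequencies in kHz; every
    entry must be strictly positive.
    """
    f = np.asarray(frequency_khz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be strictly positive (kHz)")
    k = 2.0 * np.pi * (f * 1e3) / medium.sound_speed
    return float(k) if np.isscalar(frequency_khz) else k
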