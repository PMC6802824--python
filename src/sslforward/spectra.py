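"""Spectrum containers shared across the package.

Target strength (TS, dB re 1 m^2) and volume backscattering strength
(Sv, dB re 1 m^-1) are both stored as decibel values on a strictly
increasing frequency grid in kHz, together with a validity mask.

Zero backscatter (e.g. a fluid-like body with no acoustic contrast) is
represented by an explicit sentinel value rather than -inf, so that
conversion to the linear domain maps it to exactly 0 and aggregation in
natural scale behaves additively without -inf arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Decibel sentinel meaning "exactly zero backscatter" (linear value 0).
SENTINEL_DB = -999.0


def db_to_linear(values_db: np.ndarray) -> np.ndarray:
    """10^(x/10), mapping the zero-backscatter sentinel to exactly 0."""
    v = np.asarray(values_db, dtype=float)
    out = np.where(v <= SENTINEL_DB, 0.0, 10.0 ** (v / 10.0))
    return out


def linear_to_db(values_linear: np.ndarray) -> np.ndarray:
    """10*log10(x), mapping non-positive values to the sentinel."""
    v = np.asarray(values_linear, dtype=float)
    out = np.full(v.shape, SENTINEL_DB)
    pos = v > 0
    out[pos] = 10.0 * np.log10(v[pos])
    return out


@dataclass
class Spectrum:
    """Decibel values on a masked frequency grid.

    ``mask`` is True where the value is considered valid (e.g. within the
    stated validity range of a scattering model). Sentinel values are legal
    in both masked and unmasked bins.
    """

    frequencies_khz: np.ndarray
    values_db: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frequencies_khz = np.asarray(self.frequencies_khz, dtype=float)
        self.values_db = np.asarray(self.values_db, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.frequencies_khz.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.frequencies_khz.ndim != 1:
            raise ValueError("frequency grid must be one-dimensional")
        if self.values_db.shape != self.frequencies_khz.shape:
            raise ValueError("values and frequencies must have the same shape")
        if self.mask.shape != self.frequencies_khz.shape:
            raise ValueError("mask and frequencies must have the same shape")
        if self.frequencies_khz.size and np.any(np.diff(self.frequencies_khz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def linear(self) -> np.ndarray:
        return db_to_linear(self.values_db)

    def same_grid(self, other: "Spectrum") -> bool:
        return (
            self.frequencies_khz.shape == other.frequencies_khz.shape
            and np.allclose(self.frequencies_khz, other.frequencies_khz)
        )


class TSSpectrum(Spectrum):
    """Target strength spectrum, dB re 1 m^2."""


class SvSpectrum(Spectrum):
    """Volume backscattering strength spectrum, dB re 1 m^-1."""


def sentinel_spectrum(frequencies_khz, cls=Spectrum, mask=None) -> Spectrum:
    """A spectrum of pure zero backscatter on the given grid."""
    f = np.asarray(frequencies_khz, dtype=float)
    return cls(f, np.full(f.shape, SENTINEL_DB), mask)


def resonance_peak(spectrum: Spectrum, include_masked: bool = False):
    """Locate the spectrum maximum.

    Returns ``(f_peak_khz, value_db)`` using the argmax over unmasked
    frequencies (all frequencies when ``include_masked``). Ties break
    toward the lowest frequency. Raises ``ValueError`` when no usable
    frequency remains.
    """
    if spectrum.frequencies_khz.size == 0:
        raise ValueError("empty spectrum has no peak")
    usable = np.ones(spectrum.mask.shape, bool) if include_masked else spectrum.mask
    if not np.any(usable):
        raise ValueError("all frequencies are masked; no peak")
    vals = np.where(usable, spectrum.values_db, -np.inf)
    idx = int(np.argmax(vals))  # argmax returns the first (lowest-f) maximum
    return float(spectrum.frequencies_khz[idx]), float(spectrum.values_db[idx])
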