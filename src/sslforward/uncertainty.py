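"""Parameter-uncertainty propagation by Latin-Hypercube sampling.

Scattering-model parameters taken from the literature carry uncertainty
that is represented by normal or log-normal priors centred on the
reference values. Draws are generated by Latin-Hypercube sampling (LHS):
for each parameter the probability axis is split into n equal strata and
exactly one uniform draw is taken per stratum; strata are paired across
parameters by independent seeded permutations, so the parameter space is
explored homogeneously while each marginal follows its prior exactly.

Each draw is pushed through the scattering model; the 5%, 50% and 95%
quantiles of the simulated backscattering cross-sections, taken per
frequency in the linear domain and then converted to dB, form the
predictive envelope. Body lengths are treated as measured quantities and
never sampled, and so is the orientation distribution of fluid-like
organisms (its spread already enters the model directly).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .medium import Medium
from .spectra import linear_to_db


@dataclass(frozen=True)
class ParamDistribution:
    """Prior for one scalar model parameter.

    ``kind`` is ``normal`` (location = mean) or ``lognormal`` (location and
    scale on the log axis). ``reference`` is the point value used by the
    deterministic forward model.
    """

    name: str
    kind: str
    mu: float
    sd: float
    reference: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "lognormal"):
            raise ValueError("kind must be 'normal' or 'lognormal'")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def quantile(dist: ParamDistribution, q: float) -> float:
    """Exact analytic quantile of the prior.

    Normal: mu + z_q * sd; log-normal: exp(mu + z_q * sd), with z_q the
    exact standard-normal quantile.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    z = norm.ppf(q)
    value = dist.mu + z * dist.sd
    return float(np.exp(value)) if dist.kind == "lognormal" else float(value)


@dataclass
class LHSDesign:
    """Latin-Hypercube draws: matrix of shape (n_samples, n_parameters)."""

    names: list[str]
    draws: np.ndarray
    probabilities: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return self.draws.shape[0]


def lhs_sample(dists: list[ParamDistribution], n: int, seed: int) -> LHSDesign:
    """Stratified inverse-CDF sampling.

    For every parameter exactly one probability draw falls in each stratum
    [(i-1)/n, i/n); strata are shuffled independently per parameter with a
    generator seeded from ``seed``, so the design is reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not dists:
        raise ValueError("at least one distribution is required")
    rng = np.random.default_rng(seed)
    probs = np.empty((n, len(dists)))
    values = np.empty((n, len(dists)))
    for j, dist in enumerate(dists):
        strata = rng.permutation(n)
        u = (strata + rng.uniform(size=n)) / n
        probs[:, j] = u
        z = norm.ppf(u)
        x = dist.mu + z * dist.sd
        values[:, j] = np.exp(x) if dist.kind == "lognormal" else x
    return LHSDesign([d.name for d in dists], values, probs, seed)


@dataclass
class Envelope:
    """Pointwise 5/50/95% predictive band around a modelled spectrum."""

    frequencies_khz: np.ndarray
    q05_db: np.ndarray
    q50_db: np.ndarray
    q95_db: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.q05_db > self.q50_db + 1e-12) \
                or np.any(self.q50_db > self.q95_db + 1e-12):
            raise ValueError("envelope quantiles must be ordered")


def envelope(ts_fn, base_params, dists: list[ParamDistribution],
             lengths_mm, medium: Medium, frequencies_khz,
             n: int = 1000, seed: int = 0) -> dict[float, Envelope]:
    """Predictive envelopes per length class.

    ``ts_fn(length_mm, params, medium, frequencies)`` is one of the TS
    operations; each ``ParamDistribution.name`` must match a field of
    ``base_params`` (a dataclass), otherwise a hard error is raised.
    Quantiles are computed over the n simulated cross-sections in linear
    scale, per frequency, then converted to dB.
    """
    field_names = {f.name for f in dataclasses.fields(base_params)}
    unknown = [d.name for d in dists if d.name not in field_names]
    if unknown:
        raise ValueError(
            f"distribution names {unknown} do not match parameters "
            f"{sorted(field_names)}")
    design = lhs_sample(dists, n, seed) if dists else None
    freqs = np.asarray(frequencies_khz, dtype=float)
    out: dict[float, Envelope] = {}
    for length in np.atleast_1d(np.asarray(lengths_mm, dtype=float)):
        sims = np.empty((n, freqs.size))
        for i in range(n):
            if design is None:
                params = base_params
            else:
                overrides = dict(zip(design.names, design.draws[i]))
                params = dataclasses.replace(base_params, **overrides)
            sims[i] = ts_fn(float(length), params, medium, freqs).linear
        q05, q50, q95 = np.quantile(sims, [0.05, 0.5, 0.95], axis=0)
        out[float(length)] = Envelope(freqs, linear_to_db(q05),
                                      linear_to_db(q50), linear_to_db(q95))
    return out


def aggregate_envelopes(envelopes: dict[float, Envelope],
                        densities: dict[float, float]) -> Envelope:
    """Community-level band: linear-scale density-weighted sum of the
    per-length-class quantile curves (post-aggregation labelling; the
    per-class envelopes remain available individually)."""
    lengths = list(envelopes)
    freqs = envelopes[lengths[0]].frequencies_khz
    acc = {q: np.zeros(freqs.shape) for q in ("q05", "q50", "q95")}
    from .spectra import db_to_linear
    for length, env in envelopes.items():
        d = densities[length]
        acc["q05"] += d * db_to_linear(env.q05_db)
        acc["q50"] += d * db_to_linear(env.q50_db)
        acc["q95"] += d * db_to_linear(env.q95_db)
    return Envelope(freqs, linear_to_db(acc["q05"]), linear_to_db(acc["q50"]),
                    linear_to_db(acc["q95"]))
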