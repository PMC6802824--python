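"""Forward prediction of volume backscattering from biological samples.

The forward approach predicts what an echosounder should measure from what
the nets caught: each sampled taxon contributes a volume backscattering
spectrum obtained by summing, in natural scale, the modelled target
strength of each length class weighted by its numerical density,

    Sv_j(f) = 10 log10  sum_i 10^((TS_i + 10 log10 D_i) / 10)

and the layer total is the natural-scale sum over taxa,

    Sv_predicted(f) = 10 log10  sum_j 10^(Sv_j(f) / 10).

Morphometric conventions map measured organisms onto model inputs:
silhouette areas to equivalent radii, and fish body length to swimbladder
semi-axes (swimbladder volume 2.5% of a prolate-spheroid body of minor
axis L/6, with an empirical swimbladder length-to-width ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elastic_shell import ts_elastic_shell
from .fluid_like import ts_fluid_like
from .gas_bearing import ts_gas_bearing
from .medium import Medium
from .spectra import (SvSpectrum, TSSpectrum, linear_to_db,
                      sentinel_spectrum)

MODEL_CLASSES = ("fluid_like_cylinder", "fluid_like_spheroid",
                 "elastic_shell", "gas_bearing", "excluded")

#: How record.length is to be read, by model class, unless overridden:
#: gas-bearing lengths are gas-inclusion (pneumatophore/swimbladder)
#: lengths; everything else is a body length.
LENGTH_KINDS = ("body", "gas_inclusion")


@dataclass(frozen=True)
class SampleRecord:
    """One sampled population element entering the forward model.

    ``length_mm`` follows the per-taxon convention: body length for
    fluid-like organisms, shell diameter for elastic-shell organisms and,
    for gas-bearing records, either the directly measured gas-inclusion
    length (``length_kind='gas_inclusion'``, the default) or the fish body
    length (``length_kind='body'``), from which swimbladder dimensions are
    derived. ``density_ind_m3`` is numerical density. Records with
    ``model_class='excluded'`` are carried through I/O but never modelled.
    """

    taxon: str
    model_class: str
    length_mm: float
    density_ind_m3: float
    layer: str = ""
    source: str = "net"
    length_kind: str = "gas_inclusion"

    def __post_init__(self) -> None:
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(
                f"unknown model_class {self.model_class!r}; "
                f"expected one of {MODEL_CLASSES}")
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")
        if self.density_ind_m3 < 0:
            raise ValueError("density_ind_m3 must be >= 0")
        if self.length_kind not in LENGTH_KINDS:
            raise ValueError(f"length_kind must be one of {LENGTH_KINDS}")


@dataclass
class LengthClassTable:
    """Per-taxon densities binned by length class (the D_i of the taxon sum).

    ``table`` has columns taxon, bin_left_mm, bin_right_mm, density_ind_m3;
    bins are lower-edge inclusive, upper-edge exclusive and non-overlapping
    within a taxon.
    """

    bin_width_mm: float
    table: pd.DataFrame

    def taxa(self) -> list[str]:
        return list(self.table["taxon"].unique())

    def for_taxon(self, taxon: str) -> pd.DataFrame:
        return self.table[self.table["taxon"] == taxon].reset_index(drop=True)

    def total_density(self, taxon: str) -> float:
        return float(self.for_taxon(taxon)["density_ind_m3"].sum())


@dataclass
class LayerPrediction:
    """Per-taxon and total predicted Sv spectra for one depth layer."""

    layer: str
    depth_m: float
    per_taxon: dict[str, SvSpectrum]
    total: SvSpectrum
    meta: dict = field(default_factory=dict)

    def attribution(self) -> pd.DataFrame:
        """Linear-scale fraction of the total contributed by each taxon."""
        tot = self.total.linear
        rows = {}
        with np.errstate(invalid="ignore", divide="ignore"):
            for taxon, spec in self.per_taxon.items():
                rows[taxon] = np.where(tot > 0, spec.linear / tot, np.nan)
        return pd.DataFrame(rows, index=self.total.frequencies_khz)


def bin_samples(records: list[SampleRecord], bin_width_mm: float = 0.1
                ) -> LengthClassTable:
    """Bin sample records into length classes, conserving density.

    Bins are [i*w, (i+1)*w) on an absolute grid anchored at zero; every
    record falls in exactly one bin. Excluded records are dropped here.
    An empty record list yields an empty table.
    """
    if bin_width_mm <= 0:
        raise ValueError("bin width must be positive")
    rows = []
    for rec in records:
        if rec.model_class == "excluded":
            continue
        idx = int(np.floor(rec.length_mm / bin_width_mm))
        rows.append((rec.taxon, idx * bin_width_mm,
                     (idx + 1) * bin_width_mm, rec.density_ind_m3))
    df = pd.DataFrame(rows, columns=["taxon", "bin_left_mm", "bin_right_mm",
                                     "density_ind_m3"])
    if len(df):
        df = (df.groupby(["taxon", "bin_left_mm", "bin_right_mm"],
                         as_index=False)["density_ind_m3"].sum()
                .sort_values(["taxon", "bin_left_mm"])
                .reset_index(drop=True))
    return LengthClassTable(bin_width_mm, df)


def sv_taxon(ts_by_class: list[TSSpectrum], densities: np.ndarray
             ) -> SvSpectrum:
    """Taxon Sv spectrum: natural-scale sum of sigma_bs_i * D_i per bin."""
    densities = np.asarray(densities, dtype=float)
    if len(ts_by_class) != densities.size:
        raise ValueError("one TS spectrum required per length class")
    if not ts_by_class:
        raise ValueError("at least one length class required")
    grid = ts_by_class[0]
    mask = grid.mask.copy()
    total = np.zeros(grid.frequencies_khz.shape)
    for ts, d in zip(ts_by_class, densities):
        if not grid.same_grid(ts):
            raise ValueError("TS spectra must share a common frequency grid")
        mask &= ts.mask
        total += ts.linear * d
    return SvSpectrum(grid.frequencies_khz, linear_to_db(total), mask)


def sv_total(components: list[SvSpectrum], frequencies_khz=None) -> SvSpectrum:
    """Layer total: natural-scale sum of per-taxon Sv spectra."""
    if not components:
        if frequencies_khz is None:
            raise ValueError("empty component list requires a frequency grid")
        return sentinel_spectrum(np.asarray(frequencies_khz, float), SvSpectrum)
    grid = components[0]
    mask = grid.mask.copy()
    total = np.zeros(grid.frequencies_khz.shape)
    for comp in components:
        if not grid.same_grid(comp):
            raise ValueError("components must share a common frequency grid")
        mask &= comp.mask
        total += comp.linear
    return SvSpectrum(grid.frequencies_khz, linear_to_db(total), mask)


def swimbladder_dims(body_length_mm: float, sb_length_to_width: float = 1.5
                     ) -> tuple[float, float]:
    """Swimbladder semi-axes (a, b) in mm from fish body length.

    The body is a prolate spheroid with major axis L and minor axis L/6;
    the swimbladder holds 2.5% of the body volume and is itself a prolate
    spheroid with b = ratio * a.
    """
    if body_length_mm <= 0:
        raise ValueError("body length must be positive")
    if sb_length_to_width < 1.0:
        raise ValueError("swimbladder length-to-width ratio must be >= 1")
    body_volume = (4.0 / 3.0) * np.pi * (body_length_mm / 2.0) \
        * (body_length_mm / 12.0) ** 2
    sb_volume = 0.025 * body_volume
    a = (3.0 * sb_volume / (4.0 * np.pi * sb_length_to_width)) ** (1.0 / 3.0)
    return float(a), float(sb_length_to_width * a)


def radius_from_silhouette(area_mm2: float, length_mm: float | None,
                           shape: str) -> float:
    """Cross-section radius (mm) from a silhouette area.

    The silhouette is equated to the planar projection of the model shape:
    a rectangle (cylinder), an ellipse (spheroid) or a disc. If the implied
    radius exceeds length/2 the value is still returned but a warning is
    emitted (shape/length inconsistency).
    """
    if area_mm2 <= 0:
        raise ValueError("silhouette area must be positive")
    if shape == "disc":
        return float(np.sqrt(area_mm2 / np.pi))
    if length_mm is None or length_mm <= 0:
        raise ValueError("cylinder/spheroid conversions require a length")
    if shape == "cylinder":
        a = area_mm2 / (2.0 * length_mm)
    elif shape == "spheroid":
        a = 2.0 * area_mm2 / (np.pi * length_mm)
    else:
        raise ValueError(f"unknown silhouette shape {shape!r}")
    if a > length_mm / 2.0:
        warnings.warn(
            f"silhouette area {area_mm2} mm^2 implies radius {a:.3g} mm "
            f"> length/2 for shape {shape}", stacklevel=2)
    return float(a)


def _ts_for_bin(model_class: str, length_mm: float, params, medium: Medium,
                frequencies_khz, length_kind: str,
                sb_ratio: float | None) -> TSSpectrum:
    if model_class == "fluid_like_cylinder":
        return ts_fluid_like(length_mm, params, medium, frequencies_khz)
    if model_class == "fluid_like_spheroid":
        return ts_fluid_like(length_mm, params, medium, frequencies_khz)
    if model_class == "elastic_shell":
        # length convention: shell diameter; equivalent radius = L/2
        return ts_elastic_shell(length_mm / 2.0, params, medium,
                                frequencies_khz)
    if model_class == "gas_bearing":
        if length_kind == "body":
            ratio = sb_ratio if sb_ratio is not None \
                else params.length_to_width_ratio
            _, b = swimbladder_dims(length_mm, ratio)
            gas_length = 2.0 * b
        else:
            gas_length = length_mm
        return ts_gas_bearing(gas_length, params, medium, frequencies_khz)
    raise ValueError(f"cannot model class {model_class!r}")


def predict_layer(records: list[SampleRecord], medium: Medium,
                  frequencies_khz, param_resolver,
                  bin_width_mm: float = 0.1, layer: str = "",
                  ) -> LayerPrediction:
    """Full forward pipeline for one depth layer.

    ``param_resolver(taxon, model_class)`` must return the scattering
    parameter object for the taxon (FluidLikeParams, ElasticShellParams or
    GasBearingParams) and raise ``KeyError`` for unknown taxa — unknown
    taxa are a hard error, never silently dropped. The medium's ``depth``
    sets the ambient pressure used by gas-bearing models.
    """
    freqs = np.asarray(frequencies_khz, dtype=float)
    active = [r for r in records if r.model_class != "excluded"]
    per_taxon: dict[str, SvSpectrum] = {}
    for taxon in dict.fromkeys(r.taxon for r in active):  # stable order
        recs = [r for r in active if r.taxon == taxon]
        model_class = recs[0].model_class
        if any(r.model_class != model_class for r in recs):
            raise ValueError(f"taxon {taxon!r} has inconsistent model classes")
        try:
            params = param_resolver(taxon, model_class)
        except KeyError as exc:
            raise ValueError(
                f"no scattering parameters for taxon {taxon!r} "
                f"({model_class})") from exc
        length_kind = recs[0].length_kind
        table = bin_samples(recs, bin_width_mm).for_taxon(taxon)
        occupied = table[table["density_ind_m3"] > 0]
        if not len(occupied):
            per_taxon[taxon] = sentinel_spectrum(freqs, SvSpectrum)
            continue
        ts_list = []
        for _, row in occupied.iterrows():
            mid = 0.5 * (row["bin_left_mm"] + row["bin_right_mm"])
            ts_list.append(_ts_for_bin(model_class, mid, params, medium,
                                       freqs, length_kind, None))
        per_taxon[taxon] = sv_taxon(ts_list,
                                    occupied["density_ind_m3"].to_numpy())
    total = sv_total(list(per_taxon.values()), freqs)
    return LayerPrediction(layer=layer, depth_m=medium.depth,
                           per_taxon=per_taxon, total=total,
                           meta={"bin_width_mm": bin_width_mm,
                                 "n_records": len(records)})
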