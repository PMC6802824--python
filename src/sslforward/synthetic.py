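"""Synthetic communities and layered echograms with known ground truth.

The survey's acoustic and net data are not publicly deposited, so every
pipeline stage is exercised against synthetic data instead: community
sample tables drawn from the published layer composition (taxon, length
distribution, density), and echograms built by stamping each layer's
forward-modelled spectrum into its depth band and adding independent
normal noise in the dB domain. The generator records the ground truth
(cell labels, noiseless spectra, seeds) so recovery can be tested.

The default noise SD of 2 dB is a fixture choice producing cell-quantile
bands of realistic width; it is not an estimate of any instrument's noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .config import RunConfig
from .echogram import EchogramGrid, NetTrack
from .forward import LayerPrediction, SampleRecord, predict_layer
from .medium import Medium

#: Lengths are truncated below this value (mm) when drawing communities.
MIN_LENGTH_MM = 0.05


@dataclass(frozen=True)
class TaxonSpec:
    """One taxon row of a layer community table."""

    taxon: str
    model_class: str
    mean_length_mm: float
    sd_length_mm: float
    density_ind_m3: float
    length_kind: str = "gas_inclusion"
    excluded: bool = False


@dataclass
class LayerSpec:
    """A depth layer and its community."""

    name: str
    depth_min_m: float
    depth_max_m: float
    taxa: list[TaxonSpec]
    noise_sd_db: float = 2.0

    def __post_init__(self) -> None:
        if self.depth_max_m <= self.depth_min_m:
            raise ValueError("layer depth range must have positive extent")
        if any(t.density_ind_m3 < 0 for t in self.taxa):
            raise ValueError("densities must be >= 0")

    @property
    def depth_midpoint_m(self) -> float:
        return 0.5 * (self.depth_min_m + self.depth_max_m)


def layer_spec_from_config(config: RunConfig, name: str) -> LayerSpec:
    """Build a LayerSpec from a configured community preset."""
    block = config.layer_block(name)
    taxa = []
    for row in block["taxa"]:
        taxon = row["taxon"]
        excluded = bool(row.get("excluded", False)) \
            or config.model_class_for(taxon) == "excluded"
        taxa.append(TaxonSpec(
            taxon=taxon,
            model_class=("excluded" if excluded
                         else config.model_class_for(taxon)),
            mean_length_mm=row["mean_length_mm"],
            sd_length_mm=row["sd_length_mm"],
            density_ind_m3=row["density_ind_m3"],
            length_kind=config.length_kind_for(taxon),
            excluded=excluded))
    return LayerSpec(name, block["depth_min_m"], block["depth_max_m"], taxa,
                     block.get("noise_sd_db", 2.0))


@dataclass
class GroundTruth:
    """What the generator actually put in the grid."""

    layer_names: list[str]
    cell_labels: np.ndarray            # (n_ping, n_depth) layer indices
    layer_spectra_db: dict[str, np.ndarray]
    layer_predictions: dict[str, LayerPrediction]
    noise_sd_db: dict[str, float]
    seed: int
    records: dict[str, list[SampleRecord]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def make_community(spec: LayerSpec, n_per_taxon: int = 100, seed: int = 0
                   ) -> list[SampleRecord]:
    """Draw a sample-record table for one layer.

    Lengths follow N(mean, SD) truncated at 0.05 mm; each of the
    ``n_per_taxon`` records carries density/n so the taxon total is exact.
    Excluded taxa are emitted with ``model_class='excluded'``.
    """
    if n_per_taxon < 1:
        raise ValueError("n_per_taxon must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[SampleRecord] = []
    for tspec in spec.taxa:
        if tspec.sd_length_mm == 0:
            lengths = np.full(n_per_taxon, tspec.mean_length_mm)
        else:
            a = (MIN_LENGTH_MM - tspec.mean_length_mm) / tspec.sd_length_mm
            lengths = truncnorm.rvs(a, np.inf, loc=tspec.mean_length_mm,
                                    scale=tspec.sd_length_mm,
                                    size=n_per_taxon, random_state=rng)
        model_class = "excluded" if tspec.excluded else tspec.model_class
        for length in lengths:
            records.append(SampleRecord(
                taxon=tspec.taxon, model_class=model_class,
                length_mm=float(length),
                density_ind_m3=tspec.density_ind_m3 / n_per_taxon,
                layer=spec.name, source="synthetic",
                length_kind=tspec.length_kind))
    return records


def make_layered_echogram(layers: list[LayerSpec], frequencies_khz,
                          param_resolver, n_ping_blocks: int = 30,
                          depth_bin_m: float = 1.5, seed: int = 0,
                          n_per_taxon: int = 50, bin_width_mm: float = 0.1,
                          medium: Medium | None = None,
                          ) -> tuple[EchogramGrid, GroundTruth]:
    """Layered echogram whose cells carry forward-model spectra plus noise.

    Layer depth ranges must be non-overlapping and jointly cover the grid;
    each depth bin is assigned to the layer containing its centre. Per
    layer, a community is drawn, run through the forward model at the
    layer's depth midpoint, and the resulting total spectrum is written
    into every cell of the layer with independent N(0, noise SD) dB noise.
    """
    if not layers:
        raise ValueError("at least one layer is required")
    ordered = sorted(layers, key=lambda sp: sp.depth_min_m)
    for upper, lower in zip(ordered, ordered[1:]):
        if lower.depth_min_m < upper.depth_max_m - 1e-9:
            raise ValueError(
                f"layers {upper.name!r} and {lower.name!r} overlap in depth")
    freqs = np.asarray(frequencies_khz, dtype=float)
    medium = medium or Medium()
    rng = np.random.default_rng(seed)

    top = ordered[0].depth_min_m
    bottom = ordered[-1].depth_max_m
    n_depth = int(np.round((bottom - top) / depth_bin_m))
    depth_tops = top + depth_bin_m * np.arange(n_depth)
    centers = depth_tops + depth_bin_m / 2.0

    labels = np.full(n_depth, -1)
    for j, sp in enumerate(ordered):
        labels[(centers >= sp.depth_min_m) & (centers < sp.depth_max_m)] = j
    if np.any(labels < 0):
        raise ValueError("layers do not cover the depth grid")

    spectra = {}
    predictions = {}
    all_records = {}
    for j, sp in enumerate(ordered):
        records = make_community(sp, n_per_taxon,
                                 seed=int(rng.integers(2**31)))
        all_records[sp.name] = records
        layer_medium = Medium(medium.sound_speed, medium.density,
                              sp.depth_midpoint_m, medium.temperature)
        pred = predict_layer(records, layer_medium, freqs, param_resolver,
                             bin_width_mm, layer=sp.name)
        predictions[sp.name] = pred
        spectra[sp.name] = pred.total.values_db

    sv = np.empty((n_ping_blocks, n_depth, freqs.size))
    cell_labels = np.empty((n_ping_blocks, n_depth), dtype=int)
    for j, sp in enumerate(ordered):
        bins = np.flatnonzero(labels == j)
        base = spectra[sp.name]
        noise = rng.normal(0.0, sp.noise_sd_db,
                           size=(n_ping_blocks, bins.size, freqs.size))
        sv[:, bins, :] = base[None, None, :] + noise
        cell_labels[:, bins] = j

    grid = EchogramGrid(np.arange(n_ping_blocks), depth_tops, depth_bin_m,
                        freqs, sv)
    truth = GroundTruth(
        layer_names=[sp.name for sp in ordered], cell_labels=cell_labels,
        layer_spectra_db=spectra, layer_predictions=predictions,
        noise_sd_db={sp.name: sp.noise_sd_db for sp in ordered}, seed=seed,
        records=all_records,
        params={"n_per_taxon": n_per_taxon, "bin_width_mm": bin_width_mm,
                "depth_bin_m": depth_bin_m})
    return grid, truth


def make_net_track(grid: EchogramGrid, layer_name: str, truth: GroundTruth,
                   style: str = "flat") -> NetTrack:
    """A net track confined to one layer (``flat``) or sweeping all layers
    in a W shape (``w``). The flat track keeps its headline at the layer
    top so the two cells below it stay inside the layer."""
    if layer_name not in truth.layer_names:
        raise ValueError(f"unknown layer {layer_name!r}")
    j = truth.layer_names.index(layer_name)
    bins = np.flatnonzero(truth.cell_labels[0] == j)
    if bins.size < 2:
        raise ValueError(f"layer {layer_name!r} is thinner than 2 cells")
    n_ping = grid.ping_blocks.size
    if n_ping < 10:
        raise ValueError("grid must span at least 10 ping blocks")
    if style == "flat":
        headline = grid.depth_tops_m[bins[0]]
        points = [(p, float(headline)) for p in range(n_ping)]
    elif style == "w":
        shallow = grid.depth_tops_m[0]
        deep = grid.depth_tops_m[-2]
        phase = np.abs(((np.arange(n_ping) * 4 / n_ping) % 2) - 1)
        points = [(p, float(shallow + (deep - shallow) * phase[p]))
                  for p in range(n_ping)]
    else:
        raise ValueError("style must be 'flat' or 'w'")
    return NetTrack(points, gear=f"synthetic-{style}")
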