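"""File formats: sample tables, echogram grids and net tracks.

Sample tables are UTF-8 CSV with a required header. Echogram grids have
two interchangeable encodings: a flat CSV dialect (one row per cell, one
column per frequency) and NetCDF (dimensions ping_block x depth_bin x
frequency). Round-trips are lossless for float64 Sv values, masks and
geometry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .echogram import EchogramGrid, NetTrack
from .forward import MODEL_CLASSES, SampleRecord

SAMPLE_COLUMNS = ["taxon", "model_class", "layer", "length_mm",
                  "density_ind_m3", "source", "length_kind"]


def read_samples(path) -> list[SampleRecord]:
    """Read a sample table CSV with row-addressed validation errors."""
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"sample table is missing columns {missing}")
    records = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        if row["model_class"] not in MODEL_CLASSES:
            raise ValueError(
                f"row {rowno}: unknown model_class {row['model_class']!r}")
        try:
            length = float(row["length_mm"])
            density = float(row["density_ind_m3"])
        except (TypeError, ValueError):
            raise ValueError(f"row {rowno}: non-numeric length or density")
        if not np.isfinite(length) or length <= 0:
            raise ValueError(f"row {rowno}: length must be positive")
        if not np.isfinite(density) or density < 0:
            raise ValueError(f"row {rowno}: density must be >= 0")
        records.append(SampleRecord(
            taxon=str(row["taxon"]), model_class=str(row["model_class"]),
            length_mm=length, density_ind_m3=density,
            layer=str(row.get("layer", "") or ""),
            source=str(row.get("source", "net") or "net"),
            length_kind=str(row.get("length_kind", "gas_inclusion")
                            or "gas_inclusion")))
    return records


def write_samples(records: list[SampleRecord], path) -> None:
    df = pd.DataFrame([{
        "taxon": r.taxon, "model_class": r.model_class, "layer": r.layer,
        "length_mm": r.length_mm, "density_ind_m3": r.density_ind_m3,
        "source": r.source, "length_kind": r.length_kind,
    } for r in records], columns=SAMPLE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


# ----------------------------------------------------------------------
def write_grid_csv(grid: EchogramGrid, path) -> None:
    """Flat CSV: one row per cell (ping_block, depth_top_m, cell_ok,
    sv_<frequency> ...)."""
    cols = {"ping_block": np.repeat(grid.ping_blocks, grid.depth_tops_m.size),
            "depth_top_m": np.tile(grid.depth_tops_m, grid.ping_blocks.size),
            "cell_ok": grid.cell_mask.ravel().astype(int)}
    flat = grid.sv_db.reshape(-1, grid.frequencies_khz.size)
    for j, f in enumerate(grid.frequencies_khz):
        cols[f"sv_{f:g}"] = flat[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_grid_csv(path, expected_frequencies=None) -> EchogramGrid:
    df = pd.read_csv(path, float_precision="round_trip")
    freq_cols = [c for c in df.columns if c.startswith("sv_")]
    freqs = np.array([float(c[3:]) for c in freq_cols])
    order = np.argsort(freqs)
    freqs = freqs[order]
    freq_cols = [freq_cols[i] for i in order]
    _check_frequencies(freqs, expected_frequencies)
    pings = np.unique(df["ping_block"].to_numpy())
    depths = np.unique(df["depth_top_m"].to_numpy())
    bin_height = float(np.diff(depths)[0]) if depths.size > 1 else 1.5
    df = df.sort_values(["ping_block", "depth_top_m"])
    sv = df[freq_cols].to_numpy().reshape(pings.size, depths.size,
                                          freqs.size)
    mask = df["cell_ok"].to_numpy().reshape(pings.size, depths.size) \
        .astype(bool)
    return EchogramGrid(pings, depths, bin_height, freqs, sv, mask)


def write_grid_netcdf(grid: EchogramGrid, path) -> None:
    ds = xr.Dataset(
        {"sv": (("ping_block", "depth_bin", "frequency"), grid.sv_db),
         "cell_ok": (("ping_block", "depth_bin"),
                     grid.cell_mask.astype(np.int8))},
        coords={"ping_block": grid.ping_blocks.astype(np.int32),
                "depth_bin": grid.depth_tops_m,
                "frequency": grid.frequencies_khz},
        attrs={"bin_height_m": grid.bin_height_m,
               "sv_units": "dB re 1 m-1", "frequency_units": "kHz",
               "depth_bin_convention": "upper edge, m"})
    ds.to_netcdf(path, engine="scipy")


def read_grid_netcdf(path, expected_frequencies=None) -> EchogramGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        freqs = ds["frequency"].to_numpy()
        _check_frequencies(freqs, expected_frequencies)
        return EchogramGrid(
            ds["ping_block"].to_numpy(), ds["depth_bin"].to_numpy(),
            float(ds.attrs["bin_height_m"]), freqs,
            ds["sv"].to_numpy(), ds["cell_ok"].to_numpy().astype(bool))


def _check_frequencies(freqs, expected) -> None:
    if expected is None:
        return
    expected = np.asarray(expected, dtype=float)
    if freqs.size != expected.size or not np.allclose(freqs, expected):
        offending = sorted(set(np.round(freqs, 6))
                           ^ set(np.round(expected, 6)))
        raise ValueError(
            f"grid frequencies do not match the configured bands; "
            f"offending frequencies (kHz): {offending[:20]}")


def read_grid(path, expected_frequencies=None) -> EchogramGrid:
    """Dispatch on extension: .nc -> NetCDF, otherwise CSV."""
    if str(path).endswith(".nc"):
        return read_grid_netcdf(path, expected_frequencies)
    return read_grid_csv(path, expected_frequencies)


def write_grid(grid: EchogramGrid, path) -> None:
    if str(path).endswith(".nc"):
        write_grid_netcdf(grid, path)
    else:
        write_grid_csv(grid, path)


# ----------------------------------------------------------------------
def write_track(track: NetTrack, path) -> None:
    pd.DataFrame(track.points,
                 columns=["ping_block", "headline_depth_m"]) \
        .to_csv(path, index=False, float_format="%.17g")


def read_track(path, gear: str = "net") -> NetTrack:
    df = pd.read_csv(path)
    for col in ("ping_block", "headline_depth_m"):
        if col not in df.columns:
            raise ValueError(f"track file is missing column {col!r}")
    points = [(int(r.ping_block), float(r.headline_depth_m))
              for r in df.itertuples()]
    return NetTrack(points, gear)
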