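"""Broadband echogram analysis: standardization, clustering, net tracks.

Echograms are grids of echo-integration cells (depth bin x ping block),
each carrying a volume backscattering spectrum Sv(f) on a common 2-kHz
frequency grid spanning the echosounder bands. Spectrum *shape* rather
than level drives species discrimination, so before clustering each cell
spectrum is standardized by its transducer-bandwidth-weighted mean:

    Sv_std(f) = Sv(f) - 10 log10( sum_n mean_sv_n / N_transducers )

where mean_sv_n is the natural-scale mean of the spectrum over the
bandwidth of transducer n. Segmentation uses Gaussian-mixture EM with
deterministic initialization from k equal horizontal depth bands,
reflecting the horizontally stratified structure of scattering layers.
Measured spectra along net tracks are extracted as the per-frequency
median over the two echo-integration cells below the net headline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .spectra import SENTINEL_DB, SvSpectrum, db_to_linear, linear_to_db

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Band:
    name: str
    f_min_khz: float
    f_max_khz: float
    kind: str = "FM"  # CW | FM
    use_in_clustering: bool = True

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.f_min_khz) & (freqs <= self.f_max_khz)


@dataclass
class TransducerBands:
    """Echosounder band plan plus excluded frequency intervals."""

    bands: list[Band]
    exclusions: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ordered = sorted(self.bands, key=lambda b: b.f_min_khz)
        for lo, hi in zip(ordered, ordered[1:]):
            if hi.f_min_khz < lo.f_max_khz:
                raise ValueError(
                    f"bands {lo.name} and {hi.name} overlap")

    def analysis_mask(self, freqs: np.ndarray) -> np.ndarray:
        """True where a frequency belongs to a band and is not excluded."""
        m = np.zeros(freqs.shape, dtype=bool)
        for band in self.bands:
            m |= band.contains(freqs)
        for lo, hi in self.exclusions:
            m &= ~((freqs >= lo) & (freqs <= hi))
        return m

    def clustering_mask(self, freqs: np.ndarray) -> np.ndarray:
        """Analysis mask restricted to bands used as clustering features."""
        m = np.zeros(freqs.shape, dtype=bool)
        for band in self.bands:
            if band.use_in_clustering:
                m |= band.contains(freqs)
        for lo, hi in self.exclusions:
            m &= ~((freqs >= lo) & (freqs <= hi))
        return m


def default_bands() -> TransducerBands:
    """Survey band plan: two CW channels (18, 38 kHz) and four FM sweeps;
    240-260 kHz removed (noise spikes), the 280-420 kHz band kept for
    spectra but excluded from the clustering feature space (limited
    range)."""
    return TransducerBands(
        bands=[
            Band("ES18", 18.0, 18.0, "CW"),
            Band("ES38", 38.0, 38.0, "CW"),
            Band("ES70", 47.0, 90.0, "FM"),
            Band("ES120", 95.0, 160.0, "FM"),
            Band("ES200", 180.0, 240.0, "FM"),
            Band("ES333", 280.0, 420.0, "FM", use_in_clustering=False),
        ],
        exclusions=[(240.0, 260.0)],
    )


def default_frequency_grid(bands: TransducerBands | None = None,
                           step_khz: float = 2.0) -> np.ndarray:
    """2-kHz grid over the band plan: CW centre frequencies plus a regular
    grid across each FM bandwidth."""
    bands = bands or default_bands()
    pieces = []
    for band in bands.bands:
        if band.f_min_khz == band.f_max_khz:
            pieces.append(np.array([band.f_min_khz]))
        else:
            pieces.append(np.arange(band.f_min_khz,
                                    band.f_max_khz + step_khz / 2, step_khz))
    return np.unique(np.concatenate(pieces))


@dataclass
class EchogramGrid:
    """Cell-indexed Sv spectra.

    ``sv_db`` has shape (n_ping_blocks, n_depth_bins, n_frequencies);
    ``depth_tops_m`` are the upper edges of contiguous depth bins of height
    ``bin_height_m``; ``cell_mask`` is True for usable cells.
    """

    ping_blocks: np.ndarray
    depth_tops_m: np.ndarray
    bin_height_m: float
    frequencies_khz: np.ndarray
    sv_db: np.ndarray
    cell_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ping_blocks = np.asarray(self.ping_blocks)
        self.depth_tops_m = np.asarray(self.depth_tops_m, dtype=float)
        self.frequencies_khz = np.asarray(self.frequencies_khz, dtype=float)
        self.sv_db = np.asarray(self.sv_db, dtype=float)
        expected = (self.ping_blocks.size, self.depth_tops_m.size,
                    self.frequencies_khz.size)
        if self.sv_db.shape != expected:
            raise ValueError(f"sv_db shape {self.sv_db.shape} != {expected}")
        if self.cell_mask is None:
            self.cell_mask = np.ones(expected[:2], dtype=bool)
        if self.depth_tops_m.size > 1:
            steps = np.diff(self.depth_tops_m)
            if not np.allclose(steps, self.bin_height_m):
                raise ValueError("depth bins must be contiguous")

    @property
    def n_cells(self) -> int:
        return int(self.cell_mask.sum())

    def cell_spectra(self) -> np.ndarray:
        """Masked cells flattened to (n_cells, n_freq), ping-major order."""
        return self.sv_db[self.cell_mask]

    def spectrum_at(self, i_ping: int, i_depth: int) -> SvSpectrum:
        return SvSpectrum(self.frequencies_khz, self.sv_db[i_ping, i_depth])


def band_mean_sv(spectrum: SvSpectrum, band: Band) -> float:
    """Natural-scale mean of the spectrum over one transducer bandwidth.

    Masked bins are excluded from both the numerator and the bin count;
    a fully masked band raises ``ValueError``.
    """
    sel = band.contains(spectrum.frequencies_khz) & spectrum.mask
    if not np.any(sel):
        raise ValueError(f"band {band.name} has no usable frequency bin")
    return float(db_to_linear(spectrum.values_db[sel]).mean())


def standardize(spectrum: SvSpectrum, bands: TransducerBands) -> SvSpectrum:
    """Remove the overall level: Sv(f) minus the dB value of the mean of
    the per-transducer natural-scale band means. Fully sentinel spectra
    are returned unchanged; fully masked bands are skipped with a log
    message."""
    means = []
    for band in bands.bands:
        try:
            means.append(band_mean_sv(spectrum, band))
        except ValueError:
            logger.warning("band %s fully masked; excluded from "
                           "standardization", band.name)
    if not means or all(m == 0.0 for m in means):
        return SvSpectrum(spectrum.frequencies_khz,
                          spectrum.values_db.copy(), spectrum.mask.copy())
    scalar = 10.0 * np.log10(np.sum(means) / len(means))
    out = np.where(spectrum.values_db <= SENTINEL_DB, SENTINEL_DB,
                   spectrum.values_db - scalar)
    return SvSpectrum(spectrum.frequencies_khz, out, spectrum.mask.copy())


def _standardized_matrix(grid: EchogramGrid, bands: TransducerBands
                         ) -> np.ndarray:
    cells = grid.cell_spectra()
    out = np.empty_like(cells)
    for i, row in enumerate(cells):
        out[i] = standardize(SvSpectrum(grid.frequencies_khz, row),
                             bands).values_db
    return out


def _depth_band_sizes(n_bins: int, k: int) -> list[int]:
    sizes = [n_bins // k] * k
    sizes[-1] += n_bins % k  # remainder cells go to the deepest band
    return sizes


def init_horizontal_bands(grid: EchogramGrid, k: int,
                          bands: TransducerBands | None = None,
                          standardized: bool = True) -> np.ndarray:
    """Initial cluster means from k equal horizontal depth bands.

    Each band mean is computed in natural scale per frequency over the
    band's cells, then converted to dB; deterministic by construction.
    """
    n_bins = grid.depth_tops_m.size
    if k < 1 or k > n_bins:
        raise ValueError(f"k must lie in [1, {n_bins}], got {k}")
    if standardized:
        bands = bands or default_bands()
        flat = _standardized_matrix(grid, bands)
    else:
        flat = grid.cell_spectra()
    depth_idx = np.broadcast_to(np.arange(n_bins)[None, :],
                                grid.cell_mask.shape)[grid.cell_mask]
    sizes = _depth_band_sizes(n_bins, k)
    edges = np.cumsum([0] + sizes)
    means = np.empty((k, grid.frequencies_khz.size))
    for j in range(k):
        sel = (depth_idx >= edges[j]) & (depth_idx < edges[j + 1])
        if not np.any(sel):
            raise ValueError(f"horizontal band {j} contains no cells")
        means[j] = linear_to_db(db_to_linear(flat[sel]).mean(axis=0))
    return means


@dataclass
class ClusterModel:
    """EM segmentation of an echogram.

    ``labels`` gives a cluster index in [0, k) for every unmasked cell in
    ping-major order; ``median_sv_db``/``q25``/``q75`` are per-cluster
    spectra computed from the raw (unstandardized) Sv values.
    """

    k: int
    feature_frequencies_khz: np.ndarray
    means: np.ndarray
    labels: np.ndarray
    responsibilities: np.ndarray
    median_sv_db: np.ndarray
    q25_sv_db: np.ndarray
    q75_sv_db: np.ndarray
    bic: float
    log_likelihood: float
    converged: bool


def em_cluster(grid: EchogramGrid, k: int,
               bands: TransducerBands | None = None,
               tol: float = 1e-6, max_iter: int = 500) -> ClusterModel:
    """Gaussian-mixture EM on standardized cell spectra.

    Features are the standardized spectra restricted to the clustering
    frequency mask (noise-spike exclusions and the limited-range high band
    removed). Components use diagonal covariances; initialization comes
    from ``init_horizontal_bands``, making the fit deterministic. Should a
    component end up empty it is re-seeded at the cell farthest from its
    assigned centre and the fit repeated.
    """
    bands = bands or default_bands()
    feat_mask = bands.clustering_mask(grid.frequencies_khz)
    if not np.any(feat_mask):
        raise ValueError("no frequencies available for clustering features")
    flat = _standardized_matrix(grid, bands)
    X = flat[:, feat_mask]
    if X.shape[0] < k:
        raise ValueError("fewer cells than clusters")
    means0 = init_horizontal_bands(grid, k, bands)[:, feat_mask]
    var0 = np.maximum(X.var(axis=0), 1e-6)

    for attempt in range(3):
        gm = GaussianMixture(
            n_components=k, covariance_type="diag", tol=tol,
            max_iter=max_iter, n_init=1, means_init=means0,
            weights_init=np.full(k, 1.0 / k),
            precisions_init=np.tile(1.0 / var0, (k, 1)),
            reg_covar=1e-6, random_state=0)
        gm.fit(X)
        labels = gm.predict(X)
        empty = [j for j in range(k) if not np.any(labels == j)]
        if not empty:
            break
        logger.warning("EM attempt %d left clusters %s empty; re-seeding "
                       "from farthest cells", attempt, empty)
        dist = np.linalg.norm(X - gm.means_[labels], axis=1)
        order = np.argsort(dist)[::-1]
        means0 = gm.means_.copy()
        for j, idx in zip(empty, order):
            means0[j] = X[idx]

    resp = gm.predict_proba(X)
    raw = grid.cell_spectra()
    med = np.empty((k, grid.frequencies_khz.size))
    q25 = np.empty_like(med)
    q75 = np.empty_like(med)
    for j in range(k):
        members = raw[labels == j]
        if len(members) == 0:  # still empty after retries: flat sentinel
            med[j] = q25[j] = q75[j] = SENTINEL_DB
            continue
        q25[j], med[j], q75[j] = np.quantile(members, [0.25, 0.5, 0.75],
                                             axis=0)
    return ClusterModel(
        k=k, feature_frequencies_khz=grid.frequencies_khz[feat_mask],
        means=gm.means_, labels=labels, responsibilities=resp,
        median_sv_db=med, q25_sv_db=q25, q75_sv_db=q75,
        bic=float(gm.bic(X)), log_likelihood=float(gm.score(X) * len(X)),
        converged=bool(gm.converged_))


def select_k(grid: EchogramGrid, k_range,
             bands: TransducerBands | None = None):
    """Pick the number of clusters minimizing BIC over ``k_range``.

    Returns ``(k_best, trace)`` where trace maps k to its BIC — the
    quantitative proxy for maximizing spectrum-shape diversity while
    keeping the cluster count small.
    """
    trace = {}
    for k in k_range:
        trace[int(k)] = em_cluster(grid, int(k), bands).bic
    k_best = min(trace, key=lambda k: (trace[k], k))
    return k_best, trace


@dataclass
class NetTrack:
    """Sequence of (ping_block index, headline depth m) for one tow."""

    points: list[tuple[int, float]]
    gear: str = "net"


def track_cells(grid: EchogramGrid, track: NetTrack) -> list[tuple[int, int]]:
    """The 2 echo-integration cells below the net headline at each track
    point: the first two depth bins whose tops lie at or below the
    headline depth."""
    bad = []
    cells = []
    for ping, headline in track.points:
        if ping < 0 or ping >= grid.ping_blocks.size:
            bad.append((ping, headline))
            continue
        eligible = np.flatnonzero(grid.depth_tops_m >= headline - 1e-9)
        if eligible.size < 2:
            bad.append((ping, headline))
            continue
        cells.extend((ping, int(i)) for i in eligible[:2])
    if bad:
        raise ValueError(f"track points outside grid: {bad}")
    return cells


def track_measured_sv(grid: EchogramGrid, track: NetTrack):
    """Measured layer spectrum along a net track.

    Returns ``(median SvSpectrum, q25 array, q75 array)`` with quantiles
    computed per frequency in the dB domain over the selected cells.
    """
    cells = track_cells(grid, track)
    values = np.stack([grid.sv_db[p, d] for p, d in cells])
    q25, med, q75 = np.quantile(values, [0.25, 0.5, 0.75], axis=0)
    return SvSpectrum(grid.frequencies_khz, med), q25, q75


NARROWBAND_POINTS_KHZ = (18.0, 38.0, 70.0, 120.0, 200.0, 333.0)


@dataclass
class Comparison:
    """Predicted-minus-measured discrepancy."""

    frequencies_khz: np.ndarray
    difference_db: np.ndarray
    interval_means_db: dict[str, float]
    narrowband_db: dict[float, float]


def compare(predicted: SvSpectrum, measured: SvSpectrum,
            intervals: dict[str, tuple[float, float]] | None = None
            ) -> Comparison:
    """Difference spectrum (predicted - measured) with band summaries.

    ``intervals`` maps names to (f_lo, f_hi) in kHz; the summary is the
    mean difference over the interval. Narrowband-equivalent points are
    read at the nearest grid frequency.
    """
    if not predicted.same_grid(measured):
        raise ValueError("predicted and measured spectra must share a grid")
    freqs = predicted.frequencies_khz
    diff = predicted.values_db - measured.values_db
    interval_means = {}
    for name, (lo, hi) in (intervals or {}).items():
        sel = (freqs >= lo) & (freqs <= hi)
        interval_means[name] = float(diff[sel].mean()) if sel.any() \
            else float("nan")
    narrow = {}
    for f in NARROWBAND_POINTS_KHZ:
        if freqs.size:
            idx = int(np.argmin(np.abs(freqs - f)))
            narrow[f] = float(diff[idx])
    return Comparison(freqs, diff, interval_means, narrow)
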