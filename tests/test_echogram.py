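import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from sslforward import (Band, EchogramGrid, NetTrack, SvSpectrum,
                        TransducerBands, band_mean_sv, compare,
                        default_bands, em_cluster, init_horizontal_bands,
                        select_k, standardize, track_measured_sv)

TWO_BANDS = TransducerBands([Band("A", 10.0, 20.0), Band("B", 30.0, 40.0)])
F6 = np.array([10.0, 15.0, 20.0, 30.0, 35.0, 40.0])


def grid_from_layers(layer_specs, n_ping=12, freqs=F6, noise=0.0, seed=0,
                     top=10.0, bin_m=1.5):
    """Stack constant-spectrum horizontal layers into a grid."""
    rng = np.random.default_rng(seed)
    rows = []
    for spec_db, n_bins in layer_specs:
        rows.extend([np.asarray(spec_db, dtype=float)] * n_bins)
    base = np.stack(rows)  # (n_depth, F)
    sv = np.broadcast_to(base, (n_ping,) + base.shape).copy()
    if noise:
        sv += rng.normal(0.0, noise, sv.shape)
    depth_tops = top + bin_m * np.arange(base.shape[0])
    return EchogramGrid(np.arange(n_ping), depth_tops, bin_m, freqs, sv)


class TestBandMean:
    def test_constant_band(self):
        spec = SvSpectrum(F6, np.full(6, -70.0))
        assert band_mean_sv(spec, TWO_BANDS.bands[0]) == \
            pytest.approx(1e-7, rel=1e-12)

    def test_two_bin_arithmetic(self):
        spec = SvSpectrum(np.array([10.0, 20.0]),
                          np.array([-60.0, -70.0]))
        assert band_mean_sv(spec, Band("A", 10.0, 20.0)) == \
            pytest.approx(5.5e-7, rel=1e-12)

    def test_masked_bins_excluded_from_numerator_and_count(self):
        spec = SvSpectrum(np.array([10.0, 15.0, 20.0]),
                          np.array([-60.0, -10.0, -70.0]),
                          np.array([True, False, True]))
        assert band_mean_sv(spec, Band("A", 10.0, 20.0)) == \
            pytest.approx(5.5e-7, rel=1e-12)

    def test_fully_masked_band_raises(self):
        spec = SvSpectrum(np.array([10.0, 20.0]), np.array([-60.0, -70.0]),
                          np.zeros(2, bool))
        with pytest.raises(ValueError):
            band_mean_sv(spec, Band("A", 10.0, 20.0))


class TestStandardize:
    def test_flat_spectrum_standardizes_to_zero(self):
        spec = SvSpectrum(F6, np.full(6, -70.0))
        out = standardize(spec, TWO_BANDS)
        assert out.values_db == pytest.approx(0.0, abs=1e-9)

    def test_two_band_arithmetic_oracle(self):
        vals = np.where(F6 <= 20.0, -60.0, -70.0)
        out = standardize(SvSpectrum(F6, vals), TWO_BANDS)
        scalar = 10 * np.log10((1e-6 + 1e-7) / 2.0)
        assert scalar == pytest.approx(-62.60, abs=0.01)
        assert out.values_db[:3] == pytest.approx(-60.0 - scalar, abs=1e-9)
        assert out.values_db[3:] == pytest.approx(-70.0 - scalar, abs=1e-9)

    def test_uniform_offset_invariance(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            vals = rng.uniform(-90.0, -50.0, F6.size)
            shift = rng.uniform(-20.0, 20.0)
            a = standardize(SvSpectrum(F6, vals), TWO_BANDS)
            b = standardize(SvSpectrum(F6, vals + shift), TWO_BANDS)
            assert b.values_db == pytest.approx(a.values_db, abs=1e-9)

    def test_sentinel_cells_pass_through(self):
        from sslforward import SENTINEL_DB
        spec = SvSpectrum(F6, np.full(6, SENTINEL_DB))
        out = standardize(spec, TWO_BANDS)
        assert np.all(out.values_db == SENTINEL_DB)


class TestHorizontalInit:
    def test_k1_is_overall_mean(self):
        grid = grid_from_layers([(np.full(6, -60.0), 2),
                                 (np.full(6, -80.0), 2)])
        means = init_horizontal_bands(grid, 1, TWO_BANDS,
                                      standardized=False)
        expected = 10 * np.log10((1e-6 + 1e-8) / 2.0)
        assert means[0] == pytest.approx(expected, abs=1e-9)

    def test_k2_recovers_two_constant_halves(self):
        grid = grid_from_layers([(np.full(6, -60.0), 3),
                                 (np.full(6, -80.0), 3)])
        means = init_horizontal_bands(grid, 2, TWO_BANDS,
                                      standardized=False)
        assert means[0] == pytest.approx(-60.0, abs=1e-9)
        assert means[1] == pytest.approx(-80.0, abs=1e-9)

    def test_remainder_bins_go_to_deepest_band(self):
        grid = grid_from_layers([(np.full(6, -70.0), 10)])
        n = grid.depth_tops_m.size
        from sslforward.echogram import _depth_band_sizes
        assert _depth_band_sizes(n, 3) == [3, 3, 4]

    def test_k_larger_than_bins_rejected(self):
        grid = grid_from_layers([(np.full(6, -70.0), 4)])
        with pytest.raises(ValueError):
            init_horizontal_bands(grid, 5, TWO_BANDS)


def shaped(db_low, db_high):
    """Spectrum with distinct low/high band levels (distinct shape)."""
    return np.where(F6 <= 20.0, db_low, db_high)


class TestEMCluster:
    def test_k1_single_label_and_median(self):
        grid = grid_from_layers([(shaped(-60, -70), 4)], noise=1.0)
        model = em_cluster(grid, 1, TWO_BANDS)
        assert set(model.labels) == {0}
        med = np.quantile(grid.cell_spectra(), 0.5, axis=0)
        assert model.median_sv_db[0] == pytest.approx(med, abs=1e-9)

    def test_two_layer_grid_fully_recovered(self):
        grid = grid_from_layers([(shaped(-60, -75), 4),
                                 (shaped(-75, -60), 4)], noise=1.0, seed=5)
        truth = np.repeat([0, 1], 4)
        truth = np.tile(truth, grid.ping_blocks.size)
        model = em_cluster(grid, 2, TWO_BANDS)
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_deterministic_given_grid_and_k(self):
        grid = grid_from_layers([(shaped(-60, -75), 4),
                                 (shaped(-75, -60), 4)], noise=2.0, seed=8)
        m1 = em_cluster(grid, 2, TWO_BANDS)
        m2 = em_cluster(grid, 2, TWO_BANDS)
        assert np.array_equal(m1.labels, m2.labels)
        assert m1.log_likelihood == m2.log_likelihood

    def test_cluster_medians_come_from_raw_spectra(self):
        """Medians must be reconstructable from raw Sv values alone."""
        grid = grid_from_layers([(shaped(-60, -75), 4),
                                 (shaped(-75, -60), 4)], noise=1.0, seed=3)
        model = em_cluster(grid, 2, TWO_BANDS)
        raw = grid.cell_spectra()
        for j in range(2):
            expected = np.quantile(raw[model.labels == j], 0.5, axis=0)
            assert model.median_sv_db[j] == pytest.approx(expected,
                                                          abs=1e-9)

    def test_excluded_band_absent_from_feature_space(self):
        bands = TransducerBands(
            [Band("A", 10.0, 20.0),
             Band("B", 30.0, 40.0, use_in_clustering=False)],
            exclusions=[(15.0, 15.0)])
        grid = grid_from_layers([(shaped(-60, -75), 4)], noise=0.5)
        model = em_cluster(grid, 1, bands)
        assert set(model.feature_frequencies_khz) == {10.0, 20.0}


class TestSelectK:
    # layered grids are exercised end-to-end against the synthetic-data
    # generator (see the closed-loop tests); here only the degenerate case
    def test_homogeneous_grid_prefers_smallest_k(self):
        grid = grid_from_layers([(shaped(-65, -70), 8)], noise=1.0, seed=4)
        k, trace = select_k(grid, range(2, 5), TWO_BANDS)
        assert k == 2
        assert sorted(trace) == [2, 3, 4]


class TestNetTrack:
    def test_identical_cells_recover_spectrum(self):
        grid = grid_from_layers([(shaped(-60, -70), 6)])
        track = NetTrack([(p, 10.0) for p in range(12)])
        med, q25, q75 = track_measured_sv(grid, track)
        assert med.values_db == pytest.approx(shaped(-60, -70), abs=1e-9)
        assert q25 == pytest.approx(q75, abs=1e-9)

    def test_single_point_track_median_of_two_cells(self):
        grid = grid_from_layers([(np.full(6, -60.0), 1),
                                 (np.full(6, -70.0), 1),
                                 (np.full(6, -80.0), 1)])
        track = NetTrack([(0, 10.0)])
        med, _, _ = track_measured_sv(grid, track)
        assert med.values_db == pytest.approx(-65.0, abs=1e-9)

    def test_out_of_grid_points_listed(self):
        grid = grid_from_layers([(np.full(6, -60.0), 3)])
        with pytest.raises(ValueError, match="99"):
            track_measured_sv(grid, NetTrack([(99, 10.0)]))
        with pytest.raises(ValueError):  # headline below all-but-one bin
            track_measured_sv(grid, NetTrack([(0, 14.0)]))


class TestCompare:
    def test_identical_spectra_zero_everywhere(self):
        s = SvSpectrum(F6, shaped(-60, -70))
        result = compare(s, s)
        assert result.difference_db == pytest.approx(0.0, abs=1e-12)

    def test_constructed_offset_summarized(self):
        measured = SvSpectrum(F6, np.full(6, -70.0))
        vals = np.where(F6 > 25.0, -65.0, -70.0)
        predicted = SvSpectrum(F6, vals)
        result = compare(predicted, measured,
                         intervals={"high": (25.0, 40.0)})
        assert result.interval_means_db["high"] == pytest.approx(5.0)

    def test_grid_mismatch_rejected(self):
        a = SvSpectrum(F6, np.zeros(6))
        b = SvSpectrum(F6 + 1.0, np.zeros(6))
        with pytest.raises(ValueError):
            compare(a, b)

    def test_narrowband_points_at_nearest_grid_frequency(self):
        freqs = np.array([18.0, 38.0, 69.0, 121.0, 200.0, 333.0])
        a = SvSpectrum(freqs, np.arange(6.0))
        b = SvSpectrum(freqs, np.zeros(6))
        result = compare(a, b)
        assert result.narrowband_db[70.0] == 2.0
        assert result.narrowband_db[120.0] == 3.0


def test_default_bands_match_survey_plan():
    bands = default_bands()
    names = {b.name: (b.f_min_khz, b.f_max_khz) for b in bands.bands}
    assert names["ES70"] == (47.0, 90.0)
    assert names["ES333"] == (280.0, 420.0)
    freqs = np.array([239.0, 245.0, 259.0, 261.0, 333.0])
    analysis = bands.analysis_mask(freqs)
    assert analysis.tolist() == [True, False, False, False, True]
    clustering = bands.clustering_mask(freqs)
    assert clustering.tolist() == [True, False, False, False, False]
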