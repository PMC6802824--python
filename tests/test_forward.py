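import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sslforward import (Medium, SampleRecord, TSSpectrum, bin_samples,
                        predict_layer, radius_from_silhouette,
                        resonance_peak, sv_taxon, sv_total,
                        swimbladder_dims)
from sslforward.spectra import sentinel_spectrum


def rec(taxon="euphausiids", model_class="fluid_like_cylinder", length=10.0,
        density=1.0, **kw):
    return SampleRecord(taxon=taxon, model_class=model_class,
                        length_mm=length, density_ind_m3=density, **kw)


def flat_ts(db, f=(18.0, 38.0, 120.0)):
    f = np.asarray(f)
    return TSSpectrum(f, np.full(f.shape, float(db)))


class TestBinSamples:
    def test_single_record_single_bin(self):
        t = bin_samples([rec(length=4.26, density=14.2)], 0.1)
        assert len(t.table) == 1
        assert t.total_density("euphausiids") == pytest.approx(14.2)
        row = t.table.iloc[0]
        assert row["bin_left_mm"] == pytest.approx(4.2)
        assert row["bin_right_mm"] == pytest.approx(4.3)

    def test_nearby_lengths_share_a_bin(self):
        t = bin_samples([rec(length=1.00, density=2.0),
                         rec(length=1.05, density=2.0)], 0.1)
        assert len(t.table) == 1
        assert t.table.iloc[0]["density_ind_m3"] == pytest.approx(4.0)

    def test_density_conserved_for_large_sample(self):
        rng = np.random.default_rng(42)
        lengths = rng.normal(4.26, 2.22, 1000)
        lengths = lengths[lengths > 0][:900]
        records = [rec(length=float(x), density=14.2 / 900)
                   for x in lengths]
        t = bin_samples(records, 0.1)
        assert t.total_density("euphausiids") == pytest.approx(14.2,
                                                               abs=1e-9)

    def test_empty_input_gives_empty_table(self):
        t = bin_samples([], 0.1)
        assert len(t.table) == 0

    def test_excluded_records_never_enter(self):
        t = bin_samples([rec(model_class="excluded")], 0.1)
        assert len(t.table) == 0


class TestSvAlgebra:
    def test_unit_density_is_identity(self):
        sv = sv_taxon([flat_ts(-60.0)], np.array([1.0]))
        assert sv.values_db == pytest.approx(-60.0, abs=1e-9)

    def test_density_contributes_ten_log_d(self):
        sv = sv_taxon([flat_ts(-60.0)], np.array([100.0]))
        assert sv.values_db == pytest.approx(-40.0, abs=1e-9)

    def test_two_equal_bins_add_three_db(self):
        sv = sv_taxon([flat_ts(-60.0), flat_ts(-60.0)], np.ones(2))
        assert sv.values_db == pytest.approx(10 * np.log10(2e-6), abs=1e-9)

    def test_total_of_unequal_components(self):
        total = sv_total([flat_ts(-60.0), flat_ts(-80.0)])
        assert total.values_db == pytest.approx(10 * np.log10(1.01e-6),
                                                abs=1e-9)
        assert total.values_db == pytest.approx(-59.957, abs=1e-3)

    def test_single_component_identity(self):
        comp = flat_ts(-63.2)
        total = sv_total([comp])
        assert total.values_db == pytest.approx(comp.values_db, abs=1e-12)

    def test_empty_component_list_is_sentinel(self):
        total = sv_total([], frequencies_khz=[18.0, 38.0])
        assert np.all(total.linear == 0.0)

    def test_adding_a_component_never_decreases_total(self):
        rng = np.random.default_rng(0)
        comps = [flat_ts(float(v)) for v in rng.uniform(-90, -50, 5)]
        partial = sv_total(comps[:4])
        full = sv_total(comps)
        assert np.all(full.linear >= partial.linear)

    def test_associativity_in_linear_domain(self):
        """Summing per-bin then across groups equals one merged sum."""
        ts = [flat_ts(v) for v in (-55.0, -62.0, -70.0, -48.0)]
        d = np.array([3.0, 1.0, 10.0, 0.5])
        merged = sv_taxon(ts, d)
        split = sv_total([sv_taxon(ts[:2], d[:2]), sv_taxon(ts[2:], d[2:])])
        assert split.values_db == pytest.approx(merged.values_db, abs=1e-9)

    def test_density_linearity_ten_db_per_decade(self):
        ts = [flat_ts(v) for v in (-55.0, -62.0)]
        d = np.array([3.0, 1.0])
        base = sv_taxon(ts, d)
        scaled = sv_taxon(ts, 10.0 * d)
        assert scaled.values_db - base.values_db == pytest.approx(10.0,
                                                                  abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(ts_db=st.lists(st.floats(-120.0, -20.0), min_size=1,
                          max_size=8),
           scale=st.floats(0.1, 1000.0))
    def test_scaling_all_densities_shifts_sv_uniformly(self, ts_db, scale):
        """Sv responds to a global density factor c by exactly
        10 log10(c) dB, for any TS composition."""
        ts = [flat_ts(v) for v in ts_db]
        d = np.ones(len(ts))
        base = sv_taxon(ts, d)
        scaled = sv_taxon(ts, scale * d)
        expected = 10.0 * np.log10(scale)
        assert scaled.values_db - base.values_db == pytest.approx(
            expected, abs=1e-9)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sv_taxon([flat_ts(-60.0, f=(18.0, 38.0))], np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            sv_total([flat_ts(-60.0), flat_ts(-60.0, f=(18.0, 38.0))])


class TestMorphometrics:
    def test_body_minor_axis_is_sixth_of_length(self):
        # body L = 12 mm -> minor semi-axis 1 mm enters the volume formula
        a, b = swimbladder_dims(12.0, 1.5)
        body_volume = (4 / 3) * np.pi * 6.0 * 1.0**2
        sb_volume = (4 / 3) * np.pi * a * a * b
        assert sb_volume == pytest.approx(0.025 * body_volume, rel=1e-12)

    def test_algebraic_example(self):
        a, b = swimbladder_dims(10.0, 1.5)
        assert a == pytest.approx(0.3868, abs=2e-4)
        assert b == pytest.approx(1.5 * a, rel=1e-12)

    def test_cube_scaling_with_body_length(self):
        a1, _ = swimbladder_dims(10.0, 1.5)
        a2, _ = swimbladder_dims(20.0, 1.5)
        assert a2 == pytest.approx(2.0 * a1, rel=1e-12)

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ValueError):
            swimbladder_dims(10.0, 0.8)

    @pytest.mark.parametrize("area, length, shape, expected", [
        (np.pi, None, "disc", 1.0),
        (2.0, 10.0, "cylinder", 0.1),
        (2.0, 10.0, "spheroid", 4.0 / (10 * np.pi)),
    ])
    def test_silhouette_conversions(self, area, length, shape, expected):
        assert radius_from_silhouette(area, length, shape) == \
            pytest.approx(expected, rel=1e-9)

    def test_inconsistent_silhouette_warns_but_returns(self):
        with pytest.warns(UserWarning):
            a = radius_from_silhouette(50.0, 2.0, "cylinder")
        assert a == pytest.approx(12.5)


class TestPredictLayer:
    def test_all_excluded_gives_sentinel_total(self, config, band_grid):
        records = [rec(taxon="jellyfish", model_class="excluded")]
        pred = predict_layer(records, Medium(depth=83.0), band_grid,
                             config.resolver())
        assert np.all(pred.total.linear == 0.0)

    def test_single_taxon_total_equals_component(self, config, coarse_grid):
        records = [rec(taxon="siphonophore_pneumatophore",
                       model_class="gas_bearing", length=1.23,
                       density=0.48)]
        pred = predict_layer(records, Medium(depth=83.0), coarse_grid,
                             config.resolver())
        comp = pred.per_taxon["siphonophore_pneumatophore"]
        assert pred.total.values_db == pytest.approx(comp.values_db,
                                                     abs=1e-9)

    def test_unknown_taxon_is_hard_error(self, config, coarse_grid):
        records = [rec(taxon="krakens", model_class="gas_bearing")]
        with pytest.raises(ValueError, match="krakens"):
            predict_layer(records, Medium(), coarse_grid, config.resolver())

    def test_attribution_fractions_sum_to_one(self, config, coarse_grid):
        records = [
            rec(taxon="limacina", model_class="elastic_shell", length=0.71,
                density=126.0),
            rec(taxon="siphonophore_pneumatophore",
                model_class="gas_bearing", length=1.23, density=0.48),
            rec(taxon="copepods", model_class="fluid_like_spheroid",
                length=1.41, density=126.0),
        ]
        pred = predict_layer(records, Medium(depth=83.0), coarse_grid,
                             config.resolver())
        att = pred.attribution()
        assert att.sum(axis=1).to_numpy() == pytest.approx(1.0, abs=1e-9)

    def test_deep_layer_component_ordering(self, config, band_grid):
        """Mean-length deep community: resonant gas peaks sit at or below
        38 kHz and pteropods dominate the total above 225 kHz."""
        records = [
            rec(taxon="euphausiids", model_class="fluid_like_cylinder",
                length=13.7, density=1.53),
            rec(taxon="limacina", model_class="elastic_shell", length=0.71,
                density=126.0),
            rec(taxon="copepods", model_class="fluid_like_spheroid",
                length=1.41, density=126.0),
            rec(taxon="siphonophore_pneumatophore",
                model_class="gas_bearing", length=1.23, density=0.48),
            rec(taxon="fish_no_swimbladder",
                model_class="fluid_like_cylinder", length=21.5,
                density=0.012),
        ]
        pred = predict_layer(records, Medium(depth=83.0), band_grid,
                             config.resolver())
        gas = pred.per_taxon["siphonophore_pneumatophore"]
        assert resonance_peak(gas, include_masked=True)[0] <= 38.0
        att = pred.attribution()
        high = att.loc[att.index > 225.0]
        assert (high.idxmax(axis=1) == "limacina").all()
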