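"""Watershed extrema detection and pulse-feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tetrapulse import (AnalysisParams, CellTrace, Condition, extract_features,
                        damping_summary, features_table, find_peaks_troughs,
                        smooth, yfp_rfp_background_ratio)
from tetrapulse.stats import slope_conservation_test
from tetrapulse.synthetic_data import TraceSet
from tetrapulse.protocols import reference_extrema_scan


def _trace(values, dt=15.0, yfp=None, dose=6.0):
    values = np.asarray(values, dtype=float)
    times = np.arange(len(values)) * dt
    return CellTrace(cell_id="c", condition=Condition(dose), time=times,
                     rfp=values, yfp=values if yfp is None else np.asarray(yfp))


def triangle(peak=12.0, rise_min=240.0, dt=15.0):
    up = np.arange(0, rise_min + dt, dt) * (peak / rise_min)
    return np.concatenate([up, up[-2::-1]])


class TestSmooth:
    def test_window_one_is_identity_and_constant_unchanged(self):
        x = np.array([1.0, 4.0, 2.0])
        assert np.array_equal(smooth(x, 1), x)
        assert np.allclose(smooth(np.full(7, 3.0), 3), 3.0)

    def test_shrunken_edge_means_hand_value(self):
        out = smooth([0, 3, 0, 3, 0], 3)
        assert np.allclose(out, [1.5, 1, 2, 1, 1.5])

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth([1.0, 2.0, 3.0], 2)


class TestFindPeaksTroughs:
    def test_monotone_trace_has_no_interior_peak(self):
        t = np.arange(10) * 15.0
        assert find_peaks_troughs(np.arange(10.0), t) == []

    def test_single_triangular_pulse(self):
        v = triangle()
        t = np.arange(len(v)) * 15.0
        pairs = find_peaks_troughs(v, t)
        assert pairs == [(0.0, 240.0)]

    def test_non_uniform_grid_rejected(self):
        with pytest.raises(ValueError):
            find_peaks_troughs([0.0, 1.0, 0.0], [0.0, 15.0, 40.0])

    @given(st.lists(st.floats(-5, 5, allow_nan=False, width=32),
                    min_size=3, max_size=60),
           st.sampled_from([1, 3, 5]))
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_reference_scan(self, values, window):
        params = AnalysisParams(smooth_window=window)
        times = np.arange(len(values)) * 15.0
        assert find_peaks_troughs(values, times, params) == \
            reference_extrema_scan(values, times, params)

    def test_plateau_peak_assigned_to_earliest_index(self):
        v = [0.0, 1.0, 5.0, 5.0, 5.0, 1.0, 0.0]
        t = np.arange(len(v)) * 15.0
        pairs = find_peaks_troughs(v, t, AnalysisParams(smooth_window=1))
        assert pairs == [(0.0, 30.0)]


class TestExtractFeatures:
    def test_triangular_pulse_analytic_features(self):
        f = extract_features(_trace(triangle()), "RFP")
        assert f.valid
        assert f.rise_time == 240.0
        assert f.slope == pytest.approx(3.0)
        assert f.max_level == pytest.approx(12.0)

    def test_flat_trace_invalid(self):
        f = extract_features(_trace(np.full(20, 2.0)), "RFP")
        assert not f.valid and np.isnan(f.rise_time)

    def test_offset_invariance_depends_on_baseline_subtract(self):
        base = extract_features(_trace(triangle()), "RFP")
        shifted = extract_features(_trace(triangle() + 7.0), "RFP")
        assert shifted.rise_time == base.rise_time
        assert shifted.slope == pytest.approx(base.slope)
        assert shifted.max_level == pytest.approx(base.max_level)
        raw = AnalysisParams(baseline_subtract=False)
        assert extract_features(_trace(triangle() + 7.0), "RFP", raw).max_level \
            == pytest.approx(19.0)

    def test_positive_rescaling_equivariance(self):
        base = extract_features(_trace(triangle()), "RFP")
        scaled = extract_features(_trace(3.0 * triangle()), "RFP")
        assert scaled.rise_time == base.rise_time
        assert scaled.slope == pytest.approx(3.0 * base.slope)
        assert scaled.max_level == pytest.approx(3.0 * base.max_level)

    def test_short_rise_falls_back_to_average_rate(self):
        # rise of 30 min (shorter than the 1-h window): 0 -> 6 a.u.
        v = np.array([0.0, 3.0, 6.0, 3.0, 0.0, 0.0, 0.0])
        f = extract_features(_trace(v), "RFP")
        assert f.valid and f.rise_time == 30.0
        assert f.slope == pytest.approx(6.0 / 30.0 * 60.0)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError):
            extract_features(_trace(triangle()), "GFP")


class TestNoiselessDoseResponseFeatures:
    """The dissociation between total and tetramer channels, noise-free."""

    def test_rise_time_and_slope_patterns(self, noiseless_dose_series):
        feats = features_table(noiseless_dose_series)
        by = {(r.channel, r.uv_dose): r for r in feats.itertuples()}
        doses = (3.0, 6.0, 12.0)
        for ch in ("RFP", "YFP"):
            rises = [by[(ch, d)].rise_time_min for d in doses]
            assert all(b > a for a, b in zip(rises, rises[1:]))
        rfp_slopes = [by[("RFP", d)].slope_per_h for d in doses]
        assert all(b > a for a, b in zip(rfp_slopes, rfp_slopes[1:]))
        yfp_slopes = np.array([by[("YFP", d)].slope_per_h for d in doses])
        assert (yfp_slopes.max() - yfp_slopes.min()) / yfp_slopes.max() < 0.10

    def test_knockdown_makes_tetramer_slope_dose_dependent(self, params):
        from tetrapulse import PopulationConfig, generate_population
        cfg = PopulationConfig(
            conditions=tuple(Condition(d, arc_status="knockdown")
                             for d in (3.0, 6.0, 12.0)),
            n_cells=1, duration=1440.0, cv_beta=0.0, cv_kt=0.0,
            sigma_add=0.0, seed=0)
        feats = features_table(generate_population(cfg, params))
        sub = feats[(feats.channel == "YFP") & feats.valid].sort_values("uv_dose")
        slopes = sub.slope_per_h.to_numpy()
        assert slopes[-1] > 2.0 * slopes[0]


class TestSummaries:
    def test_identical_channels_give_unit_damping_ratio(self):
        traces = [CellTrace(cell_id=f"c{d}_{i}", condition=Condition(d),
                            time=np.arange(33) * 15.0,
                            rfp=triangle(peak=10 + i),
                            yfp=triangle(peak=10 + i))
                  for d in (3.0, 6.0) for i in range(3)]
        out = damping_summary(TraceSet(traces=traces), reference_dose=3.0)
        assert np.allclose(out["median_ratio"], 1.0)
        assert np.allclose(out["normalized_ratio"], 1.0)

    def test_scaling_yfp_scales_ratio_linearly(self):
        traces = [CellTrace(cell_id=f"c{i}", condition=Condition(3.0),
                            time=np.arange(33) * 15.0,
                            rfp=triangle(), yfp=0.5 * triangle())
                  for i in range(3)]
        out = damping_summary(TraceSet(traces=traces), reference_dose=3.0)
        assert np.allclose(out["median_ratio"], 0.5)

    def test_missing_reference_dose_rejected(self):
        traces = [CellTrace(cell_id="c0", condition=Condition(6.0),
                            time=np.arange(33) * 15.0,
                            rfp=triangle(), yfp=triangle())]
        with pytest.raises(ValueError, match="reference dose"):
            damping_summary(TraceSet(traces=traces), reference_dose=3.0)

    def test_background_ratio_self_normalization(self):
        traces = [CellTrace(cell_id=f"c{i}",
                            condition=Condition(6.0, genotype="L344P"),
                            time=np.arange(33) * 15.0,
                            rfp=triangle() + 5.0, yfp=0.1 * triangle() + 1.0)
                  for i in range(5)]
        summary, per_cell = yfp_rfp_background_ratio(TraceSet(traces=traces))
        assert summary["L344P"] == pytest.approx(1.0)
        assert per_cell["normalized_ratio"].median() == pytest.approx(1.0)

    def test_background_ratio_requires_reference_genotype(self):
        traces = [CellTrace(cell_id="c0", condition=Condition(6.0),
                            time=np.arange(33) * 15.0,
                            rfp=triangle() + 5.0, yfp=triangle())]
        with pytest.raises(ValueError, match="reference genotype"):
            yfp_rfp_background_ratio(TraceSet(traces=traces))

    def test_invalid_cells_are_excluded_from_feature_stats(self, params):
        flat = CellTrace(cell_id="flat", condition=Condition(3.0),
                         time=np.arange(33) * 15.0,
                         rfp=np.full(33, 5.0), yfp=np.full(33, 5.0))
        pulse = [CellTrace(cell_id=f"c{d}_{i}", condition=Condition(d),
                           time=np.arange(33) * 15.0,
                           rfp=triangle(peak=10.0 + i), yfp=triangle())
                 for d in (3.0, 6.0) for i in range(6)]
        feats = features_table(TraceSet(traces=[flat] + pulse))
        assert (~feats[feats.cell_id == "flat"]["valid"]).all()
        rep = slope_conservation_test(feats, "RFP")
        assert rep.n_per_dose == (6, 6)
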