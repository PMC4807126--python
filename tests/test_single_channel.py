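"""Idealization, histograms, dwell summaries and slope conductance."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ikstools import (
    AnalysisConfig,
    build_allpoints_histogram,
    detect_active_sweeps,
    estimate_slope_conductance,
    first_latency,
    fit_histogram_peaks,
    idealize_sweeps,
    idealize_trace,
    simulate_single_channel_sweeps,
    summarize_dwells,
)
from ikstools import constructs as C
from ikstools.events import (events_from_levels, levels_from_events,
                             merge_short_runs, runs)
from ikstools.single_channel import IdealizedTrace
from ikstools.trace_io import ConfigurationError, ProtocolStep, SweepSet

PROTO = C.single_channel_protocol("EQ")


def _trace(samples, fs=1000.0, cfg=None, **kw):
    return idealize_trace(np.asarray(samples, float), fs,
                          cfg or AnalysisConfig(), **kw)


class TestIdealize:
    def test_nearest_level_classification(self):
        """A 0.35 pA opening lands on the 0.29 level (nearer than 0.44)."""
        fs = 1000.0
        x = np.concatenate([np.zeros(500), np.full(500, 0.35), np.zeros(500)])
        tr = _trace(x, fs)
        assert [e[0] for e in tr.events] == [0, 4, 0]
        level, start, dur = tr.events[1]
        assert start == pytest.approx(0.5)
        assert dur == pytest.approx(0.5)

    def test_all_zero_sweep_is_single_closed_event(self):
        tr = _trace(np.zeros(2000))
        assert tr.events == [(0, 0.0, 2.0)]
        assert tr.is_blank

    def test_min_dwell_below_two_samples_rejected(self):
        cfg = AnalysisConfig(min_dwell_s=1e-4)
        with pytest.raises(ConfigurationError, match="min_dwell"):
            _trace(np.zeros(100), fs=1000.0, cfg=cfg)

    def test_oracle_equivalence_with_generator_log(self, cfg):
        """Idealizing noiseless, unfiltered simulator output reproduces the
        simulator's own event log exactly (after identical discretization
        and sub-resolution merging on both sides)."""
        m = dataclasses.replace(C.SINGLE_CHANNEL["EQ"], noise_sd_pA=0.0,
                                filter_cutoff_Hz=None, p_blank=0.0)
        fs = 10_000.0
        s = simulate_single_channel_sweeps(m, PROTO, 20, fs, seed=17)
        sl = s.test_step_slice()
        n_step = sl.stop - sl.start
        ladder = np.asarray(m.level_amplitudes_pA)
        min_n = int(round(cfg.min_dwell_s * fs))
        for i in range(s.n_sweeps):
            got = idealize_trace(s.sweeps[i, sl], fs, cfg, sweep_id=i)
            truth_levels = levels_from_events(s.event_logs[i], fs, n_step)
            truth_levels = merge_short_runs(truth_levels, ladder, min_n)
            expected = events_from_levels(truth_levels, fs)
            assert got.events == expected, f"sweep {i}"


class TestDetectActive:
    def test_all_zero_set_all_blank(self, cfg):
        s = SweepSet("c", "EQ", 1000.0, PROTO, np.zeros((4, 5000)))
        active, blank = detect_active_sweeps(s, cfg)
        assert active == [] and blank == [0, 1, 2, 3]

    def test_single_constructed_event_found(self, cfg):
        sweeps = np.zeros((5, 5000))
        sweeps[3, 1000:1200] = 0.44  # 200 ms at 0.44 pA inside the step
        s = SweepSet("c", "EQ", 1000.0, PROTO, sweeps)
        active, _ = detect_active_sweeps(s, cfg)
        assert active == [3]

    def test_active_fraction_matches_blank_probability(self, eq_set, cfg):
        """p_blank = 0.3 plus latency censoring predicts the active
        fraction within 3 binomial SE."""
        m = C.SINGLE_CHANNEL["EQ"]
        mu = m.first_latency_mean_s - m.first_latency_offset_s
        w = 4.0 - m.first_latency_offset_s
        p_active = (1 - m.p_blank) * (1 - np.exp(-w / mu))
        active, _ = detect_active_sweeps(eq_set, cfg)
        n = eq_set.n_sweeps
        se = np.sqrt(p_active * (1 - p_active) / n)
        assert abs(len(active) / n - p_active) <= 3 * se


class TestHistogram:
    def test_constant_trace_single_bin(self, cfg):
        s = SweepSet("c", "EQ", 1000.0, PROTO,
                     np.full((1, 5000), 0.44))
        h = build_allpoints_histogram(s, [0], cfg)
        assert h.counts.max() == h.total
        center = h.centers_pA[np.argmax(h.counts)]
        assert abs(center - 0.44) <= cfg.histogram_bin_pA

    def test_two_level_mass_ratio_exact(self, cfg):
        """30%/70% of step time at 0/0.29 pA gives a 3:7 bin-mass split."""
        fs = 1000.0
        n_step = 4000
        sweep = np.zeros(5000)
        sweep[250:250 + int(0.3 * n_step)] = 0.0
        sweep[250 + int(0.3 * n_step):250 + n_step] = 0.29
        s = SweepSet("c", "EQ", fs, PROTO, sweep[None, :])
        h = build_allpoints_histogram(s, [0], cfg)
        at_zero = h.counts[np.argmin(np.abs(h.centers_pA - 0.0))]
        at_029 = h.counts[np.argmin(np.abs(h.centers_pA - 0.29))]
        assert at_zero / at_029 == pytest.approx(3 / 7)

    def test_all_sweeps_histogram_has_larger_zero_mass(self, eq_set, cfg):
        """Removing blank sweeps limits the 0-amplitude peak."""
        active, _ = detect_active_sweeps(eq_set, cfg)
        h_active = build_allpoints_histogram(eq_set, active, cfg)
        h_all = build_allpoints_histogram(eq_set, range(eq_set.n_sweeps),
                                          cfg, active_only=False)

        def zero_frac(h):
            i = np.digitize(0.0, h.bin_edges_pA) - 1
            return h.counts[i - 1:i + 2].sum() / h.total

        assert zero_frac(h_all) > zero_frac(h_active)

    def test_empty_id_set_rejected(self, eq_set, cfg):
        with pytest.raises(ValueError, match="empty"):
            build_allpoints_histogram(eq_set, [], cfg)


class TestGaussianPeaks:
    def test_single_gaussian_recovered(self, cfg):
        """Samples from N(0.45, 0.04) yield a dominant peak within 0.02."""
        rng = np.random.default_rng(3)
        sweep = rng.normal(0.45, 0.04, 5000)
        s = SweepSet("c", "EQ", 1000.0, PROTO, sweep[None, :])
        h = build_allpoints_histogram(s, [0], cfg)
        pk = fit_histogram_peaks(h, cfg)
        assert abs(pk.dominant_open_peak_pA - 0.45) <= 0.02

    def test_weights_sum_to_one(self, eq_set, cfg):
        active, _ = detect_active_sweeps(eq_set, cfg)
        pk = fit_histogram_peaks(
            build_allpoints_histogram(eq_set, active, cfg), cfg)
        assert pk.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestDwells:
    def test_single_event_full_open_share(self, cfg):
        ev = [(0, 0.0, 1.0), (5, 1.0, 0.5), (0, 1.5, 2.5)]
        tr = IdealizedTrace(sweep_id=0, events=ev, duration_s=4.0)
        dw = summarize_dwells([tr], cfg)
        assert dw.table.percent_of_open_time.iloc[5] == pytest.approx(100.0)
        assert dw.first_latency_mean_s == pytest.approx(1.0)

    def test_percentages_sum_to_100_and_time_conserved(self, eq_set, cfg):
        active, _ = detect_active_sweeps(eq_set, cfg)
        traces = idealize_sweeps(eq_set, cfg, active)
        dw = summarize_dwells(traces, cfg)
        assert dw.table.percent_of_open_time.iloc[1:].sum() == \
            pytest.approx(100.0, abs=1e-6)
        step_s = eq_set.test_step.duration_s
        assert dw.table.total_s.sum() == pytest.approx(step_s * len(active),
                                                       rel=1e-9)

    def test_no_open_time_rejected(self, cfg):
        tr = IdealizedTrace(0, [(0, 0.0, 4.0)], 4.0)
        with pytest.raises(ValueError, match="no open time"):
            summarize_dwells([tr], cfg)

    def test_closed_mean_excludes_first_latency(self, cfg):
        # latency 1.0 s, one intraburst closure of 0.2 s
        ev = [(0, 0.0, 1.0), (4, 1.0, 0.5), (0, 1.5, 0.2), (4, 1.7, 2.3)]
        tr = IdealizedTrace(0, ev, 4.0)
        dw = summarize_dwells([tr], cfg)
        assert dw.closed_mean_excluding_first_latency_s == pytest.approx(0.2)


class TestFirstLatency:
    def test_constructed_opening_times(self):
        tr = IdealizedTrace(0, [(0, 0.0, 1.0), (3, 1.0, 3.0)], 4.0)
        assert first_latency(tr) == pytest.approx(1.0)
        tr0 = IdealizedTrace(0, [(3, 0.0, 4.0)], 4.0)
        assert first_latency(tr0) == 0.0

    def test_blank_sweep_flagged(self):
        tr = IdealizedTrace(0, [(0, 0.0, 4.0)], 4.0)
        assert first_latency(tr) is None


class TestSlopeConductance:
    def test_single_point_chord(self, cfg):
        """0.45 pA at +60 mV through -84 mV is 0.45/0.144 ~ 3.1 pS."""
        fit = estimate_slope_conductance([(60.0, 0.45)], cfg)
        assert fit.gamma_pS == pytest.approx(0.45 / 0.144, rel=1e-9)

    def test_exact_line_recovery(self, cfg):
        v = np.array([20.0, 40.0, 60.0, 80.0])
        amps = 1.3e-3 * (v + 84.0)  # 1.3 pS line through -84 mV
        fit = estimate_slope_conductance(list(zip(v, amps)), cfg)
        assert fit.gamma_pS == pytest.approx(1.3, rel=1e-12)

    def test_permutation_and_anchor_invariance(self, cfg):
        pts = [(20.0, 0.3), (60.0, 0.45), (80.0, 0.52)]
        g1 = estimate_slope_conductance(pts, cfg).gamma_pS
        g2 = estimate_slope_conductance(pts[::-1], cfg).gamma_pS
        g3 = estimate_slope_conductance(pts + [(-84.0, 0.0)], cfg).gamma_pS
        assert g1 == pytest.approx(g2, rel=1e-12)
        assert g1 == pytest.approx(g3, rel=1e-12)

    def test_all_points_at_reversal_rejected(self, cfg):
        with pytest.raises(ValueError, match="reversal"):
            estimate_slope_conductance([(-84.0, 0.0)], cfg)


class TestMergeShortRuns:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=1, max_size=60),
           st.integers(2, 5))
    def test_conserves_samples_and_removes_short_runs(self, levels, min_n):
        amps = [0.0, 0.1, 0.2, 0.4]
        out = merge_short_runs(np.array(levels), amps, min_n)
        assert out.size == len(levels)
        vals, _, lens = runs(out)
        if len(vals) > 1:
            assert lens.min() >= min_n
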