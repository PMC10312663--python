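"""Zone metrics: closed-form checks, brute-force oracles for peak detection
and extrema, and the up/down mode-symmetry property."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from casig.synthetic import TraceModel, eval_trace, make_trace_set
from casig.traces import (
    AnalysisConfig,
    StimulationZone,
    analyze_traceset,
    analyze_zone,
    compute_auc,
    compute_baseline,
    compute_threshold,
    detect_onset,
    detect_peaks,
    first_peak_metrics,
    parse_zones,
    zone_extremum,
)

ZONE = StimulationZone(20.0, 100.0)
CFG = AnalysisConfig(mode="agonist", baseline_window=15.0, threshold_k=3.0,
                     min_prominence=0.1, min_peak_distance=10.0,
                     smoothing_width=1)


def brute_force_peaks(times, values, zone, baseline, cfg):
    """Independent enumeration: shrinking-window smoothing, exhaustive
    local-maximum scan, exact topographic prominence by walking to the
    nearest higher point on each side, then greedy distance suppression."""
    v = np.asarray(values, dtype=float)
    h = cfg.smoothing_width // 2
    sm = np.array([v[max(0, i - h): i + h + 1].mean() for i in range(v.size)])
    sel = [i for i, t in enumerate(times) if zone.start <= t < zone.end]
    seg = sm[sel]
    seg_t = np.asarray(times)[sel]
    n = seg.size
    cands = []
    i = 1
    while i < n - 1:
        if seg[i] > seg[i - 1]:
            j = i
            while j < n - 1 and seg[j + 1] == seg[i]:
                j += 1
            if j < n - 1 and seg[j + 1] < seg[i]:
                cands.append(i)
            i = j + 1
        else:
            i += 1
    proms = []
    for p in cands:
        lmin = seg[p]
        i = p
        while i > 0 and seg[i - 1] <= seg[p]:
            i -= 1
            lmin = min(lmin, seg[i])
        rmin = seg[p]
        i = p
        while i < n - 1 and seg[i + 1] <= seg[p]:
            i += 1
            rmin = min(rmin, seg[i])
        proms.append(seg[p] - max(lmin, rmin))
    min_prom = cfg.min_prominence * (seg.max() - baseline) if n else 0.0
    kept = [(p, pr) for p, pr in zip(cands, proms) if pr >= min_prom]
    order = sorted(range(len(kept)), key=lambda k: (-seg[kept[k][0]], kept[k][0]))
    chosen = []
    for k in order:
        t_k = seg_t[kept[k][0]]
        if all(abs(t_k - seg_t[kept[j][0]]) >= cfg.min_peak_distance
               for j in chosen):
            chosen.append(k)
    chosen.sort(key=lambda k: kept[k][0])
    return seg_t[[kept[k][0] for k in chosen]], seg[[kept[k][0] for k in chosen]]


class TestComputeBaseline:
    def test_constant_trace(self):
        t = np.arange(120.0)
        b, sd = compute_baseline(t, np.full(120, 3.5), ZONE, 15.0)
        assert b == 3.5 and sd == 0.0

    def test_three_sample_closed_form(self):
        t = np.arange(25.0)
        v = np.zeros(25)
        v[17:20] = [1.0, 2.0, 3.0]
        b, sd = compute_baseline(t, v, ZONE, 3.0)
        assert b == 2.0 and abs(sd - 1.0) < 1e-12

    def test_clipped_window_warns(self):
        t = np.arange(30.0)
        with pytest.warns(UserWarning, match="clipped"):
            compute_baseline(t, np.ones(30), StimulationZone(5, 20), 10.0)

    def test_too_few_samples_error(self):
        t = np.arange(30.0)
        with pytest.raises(ValueError, match="need >= 3"), \
                pytest.warns(UserWarning, match="clipped"):
            compute_baseline(t, np.ones(30), StimulationZone(2, 20), 10.0)

    def test_noise_sd_estimate(self):
        rng = np.random.default_rng(12)
        t = np.arange(250.0)
        v = rng.normal(1.0, 0.5, 250)
        _, sd = compute_baseline(t, v, StimulationZone(200, 240), 200.0)
        assert 0.4 <= sd <= 0.6


class TestComputeThreshold:
    def test_upward(self):
        assert abs(compute_threshold(1.0, 0.1, 3.0, "agonist") - 1.3) < 1e-12

    def test_downward(self):
        assert abs(compute_threshold(1.0, 0.1, 3.0, "inhibitor") - 0.7) < 1e-12

    def test_floor_when_noise_free(self):
        assert compute_threshold(1.0, 0.0, 3.0, "agonist", abs_min=0.05) == 1.05


class TestDetectOnset:
    def test_step_crossing(self):
        t = np.arange(120.0)
        v = np.where(t >= 25, 10.0, 0.0)
        assert detect_onset(t, v, ZONE, 5.0, "above") == 25.0

    def test_never_crossing_is_missing(self):
        t = np.arange(120.0)
        assert detect_onset(t, np.ones(120), ZONE, 5.0, "above") is None

    def test_descending_staircase_matches_scan(self):
        t = np.arange(60.0)
        v = 10.0 - np.floor(t / 4)
        zone = StimulationZone(10, 59)
        threshold = 6.5
        got = detect_onset(t, v, zone, threshold, "below")
        expect = next(t[i] for i in range(60)
                      if zone.start <= t[i] < zone.end and v[i] < threshold)
        assert got == expect


class TestDetectPeaks:
    def test_flat_trace_no_peaks(self):
        t = np.arange(120.0)
        assert len(detect_peaks(t, np.ones(120), ZONE, 1.0, CFG)) == 0

    def test_single_triangular_bump(self):
        t = np.arange(120.0)
        v = np.maximum(0.0, 10.0 - np.abs(t - 30.0))
        peaks = detect_peaks(t, v, ZONE, 0.0, CFG)
        assert len(peaks) == 1
        assert peaks.peak_times[0] == 30.0

    def test_two_gaussian_bumps(self):
        t = np.arange(120.0)
        v = 5 * np.exp(-0.5 * ((t - 40) / 4) ** 2) \
            + 3 * np.exp(-0.5 * ((t - 80) / 4) ** 2)
        peaks = detect_peaks(t, v, ZONE, 0.0, CFG)
        assert len(peaks) == 2
        assert abs(peaks.peak_times[0] - 40.0) <= 1.0
        assert abs(peaks.peak_times[1] - 80.0) <= 1.0

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("width", [1, 3, 5])
    def test_matches_brute_force_on_random_walks(self, seed, width):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(60, 500))
        t = np.arange(n) * 0.5
        v = np.cumsum(rng.standard_normal(n)) * 0.3
        zone = StimulationZone(t[5], t[-3])
        cfg = dataclasses.replace(CFG, smoothing_width=width,
                                  min_peak_distance=float(rng.uniform(0, 8)))
        baseline = float(v[:5].mean())
        peaks = detect_peaks(t, v, zone, baseline, cfg)
        bt, bv = brute_force_peaks(t, v, zone, baseline, cfg)
        assert np.array_equal(peaks.peak_times, bt)
        assert np.allclose(peaks.peak_values, bv, atol=1e-12)


class TestFirstPeakMetrics:
    def test_linear_ramp(self):
        t = np.arange(40.0)
        v = np.clip(t - 10.0, 0.0, 10.0)
        rise, slope = first_peak_metrics(t, v, 10.0, 20.0)
        assert rise == 10.0
        assert abs(slope - 1.0) < 1e-12

    def test_degenerate_interval(self):
        t = np.arange(40.0)
        rise, slope = first_peak_metrics(t, np.ones(40), 15.0, 15.0)
        assert rise == 0.0
        assert math.isnan(slope)

    def test_piecewise_ramp_max_segment(self):
        t = np.arange(0.0, 16.0)
        v = np.concatenate([np.zeros(1), np.cumsum(
            [0.5] * 5 + [2.0] * 5 + [1.0] * 5)])
        rise, slope = first_peak_metrics(t, v, 0.0, 15.0)
        assert abs(slope - 2.0) < 1e-12

    def test_onset_after_peak_rejected(self):
        with pytest.raises(ValueError):
            first_peak_metrics(np.arange(10.0), np.ones(10), 5.0, 3.0)


class TestAuc:
    def test_trace_at_baseline_zero(self):
        t = np.arange(120.0)
        assert compute_auc(t, np.full(120, 2.0), ZONE, 2.0) == 0.0

    def test_rectangular_pulse(self):
        t = np.arange(120.0)
        v = np.where((t >= 30) & (t < 80), 2.0, 0.0)
        # trapezoid: 49 full frames + two half-frame edges = height * width
        assert abs(compute_auc(t, v, ZONE, 0.0) - 100.0) < 1e-12

    def test_triangle(self):
        t = np.arange(120.0)
        v = np.maximum(0.0, 4.0 * (1 - np.abs(t - 50.0) / 10.0))
        auc = compute_auc(t, v, ZONE, 0.0)
        assert abs(auc - 40.0) <= 4.0 * 1.0  # within one frame correction

    @given(st.integers(0, 2**31 - 1))
    def test_additivity_at_sample_boundary(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(60.0)
        v = rng.normal(1.0, 0.5, 60)
        a, b, c = 5.0, 30.0, 55.0
        whole = compute_auc(t, v, StimulationZone(a, c), 1.0)
        parts = compute_auc(t, v, StimulationZone(a, b), 1.0) \
            + compute_auc(t, v, StimulationZone(b, c), 1.0)
        assert abs(whole - parts) < 1e-9


class TestZoneExtremum:
    def test_rising_ramp_max_at_end(self):
        t = np.arange(120.0)
        tm, vm = zone_extremum(t, t.copy(), ZONE, "max")
        assert tm == 99.0 and vm == 99.0

    def test_falling_ramp_min_at_end(self):
        t = np.arange(120.0)
        tm, vm = zone_extremum(t, -t, ZONE, "min")
        assert tm == 99.0 and vm == -99.0

    def test_tie_goes_to_earliest(self):
        t = np.arange(120.0)
        v = np.zeros(120)
        v[[40, 60]] = 7.0
        tm, _ = zone_extremum(t, v, ZONE, "max")
        assert tm == 40.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_linear_scan(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(120.0)
        v = rng.normal(size=120)
        for direction, pick in (("max", np.argmax), ("min", np.argmin)):
            tm, vm = zone_extremum(t, v, ZONE, direction)
            idx = [i for i in range(120) if ZONE.start <= t[i] < ZONE.end]
            best = idx[int(pick(v[idx]))]
            assert tm == t[best] and vm == v[best]


class TestAnalyzeZone:
    def test_agonist_closed_form(self):
        m = TraceModel("agonist", onset_time=30, peak_time=45, amplitude=5,
                       decay_tau=20)
        ts = make_trace_set([m], dt=1.0, n_frames=120, baselines=0.0)
        z = analyze_zone(ts.times, ts.values[:, 0], ZONE, CFG, roi_id=1)
        assert abs(z.latency_s - 10.0) <= 1.0  # onset one sample after ramp start
        assert abs(z.first_peak_height - 5.0) < 1e-9
        assert z.peak_count == 1
        assert abs(z.max_slope_per_s - 5.0 / 15.0) < 1e-9
        assert abs(z.rise_time_s - 15.0) <= 1.0

    def test_inhibitor_closed_form(self):
        m = TraceModel("inhibitor", onset_time=30, peak_time=45, amplitude=-3)
        ts = make_trace_set([m], dt=1.0, n_frames=120, baselines=2.0)
        cfg = dataclasses.replace(CFG, mode="inhibitor")
        z = analyze_zone(ts.times, ts.values[:, 0], ZONE, cfg, roi_id=1)
        assert z.max_slope_per_s < 0
        assert abs(z.max_slope_per_s + 3.0 / 15.0) < 1e-9
        assert abs(z.extremum_value - (-1.0)) < 1e-9
        # fall time: onset to zone minimum
        assert abs(z.rise_time_s - (z.extremum_time_s - z.onset_time_s)) < 1e-9
        assert z.secant_slope_per_s < 0

    def test_flat_trace_all_missing(self):
        t = np.arange(120.0)
        z = analyze_zone(t, np.full(120, 1.0), ZONE, CFG)
        assert z.peak_count == 0
        assert z.auc == 0.0
        assert math.isnan(z.onset_time_s) and math.isnan(z.latency_s)
        assert z.baseline == 1.0

    def test_threshold_k_monotone_latency(self):
        m = TraceModel("agonist", onset_time=30, peak_time=45, amplitude=5,
                       decay_tau=20)
        ts = make_trace_set([m], dt=1.0, n_frames=120, baselines=1.0,
                            noise_sd=0.2, seed=4)
        latencies = []
        for k in (0.5, 1.0, 2.0, 4.0, 8.0):
            cfg = dataclasses.replace(CFG, threshold_k=k)
            z = analyze_zone(ts.times, ts.values[:, 0], ZONE, cfg)
            latencies.append(z.latency_s if not math.isnan(z.latency_s)
                             else math.inf)
        assert all(a <= b for a, b in zip(latencies, latencies[1:]))

    @pytest.mark.parametrize("seed", range(8))
    def test_inhibitor_mirrors_soce_exactly(self, seed):
        """Downward analysis is the exact mirror of the upward (soce)
        analysis on the reflected trace, field for field, even with noise."""
        rng = np.random.default_rng(seed)
        m = TraceModel("inhibitor", onset_time=float(rng.uniform(25, 35)),
                       peak_time=float(rng.uniform(40, 60)),
                       amplitude=float(-rng.uniform(1, 4)))
        ts = make_trace_set([m], dt=1.0, n_frames=120, baselines=2.0,
                            noise_sd=0.05, seed=seed)
        v = ts.values[:, 0]
        cfg_inh = dataclasses.replace(CFG, mode="inhibitor", smoothing_width=3)
        cfg_soce = dataclasses.replace(CFG, mode="soce", smoothing_width=3)
        zi = analyze_zone(ts.times, v, ZONE, cfg_inh)
        b = zi.baseline
        zs = analyze_zone(ts.times, 2 * b - v, ZONE, cfg_soce)
        tol = 1e-9
        assert abs(zi.baseline - zs.baseline) < tol
        assert abs(zi.threshold - (2 * b - zs.threshold)) < tol
        assert zi.onset_time_s == zs.onset_time_s
        assert zi.latency_s == zs.latency_s
        assert abs(zi.rise_time_s - zs.rise_time_s) < tol
        assert abs(zi.max_slope_per_s + zs.max_slope_per_s) < tol
        assert abs(zi.secant_slope_per_s + zs.secant_slope_per_s) < tol
        assert abs(zi.auc - zs.auc) < tol
        assert zi.peak_count == zs.peak_count
        assert zi.extremum_time_s == zs.extremum_time_s
        assert abs(zi.extremum_value - (2 * b - zs.extremum_value)) < tol


class TestAnalyzeTraceset:
    def test_row_per_roi_and_zone(self):
        models = [TraceModel("agonist", 30, 45, 5, 20)] * 3
        ts = make_trace_set(models, n_frames=220)
        zones = [StimulationZone(20, 100), StimulationZone(120, 200)]
        df = analyze_traceset(ts, zones, CFG)
        assert len(df) == 6
        assert set(df["roi_id"]) == {1, 2, 3}
        assert set(df["zone_index"]) == {0, 1}

    def test_empty_traceset_header_only(self, tmp_path):
        from casig.stack_io import TraceSet
        from casig.traces import METRICS_COLUMNS, write_metrics_csv

        ts = TraceSet(times=np.arange(120.0), values=np.empty((120, 0)),
                      roi_ids=np.empty(0, dtype=int))
        df = analyze_traceset(ts, [ZONE], CFG)
        assert len(df) == 0
        path = tmp_path / "m.csv"
        write_metrics_csv(df, path)
        assert path.read_text().strip() == ",".join(METRICS_COLUMNS)

    def test_latency_recovered_across_rois(self):
        rng = np.random.default_rng(77)
        onsets = rng.uniform(25, 60, size=10)
        models = [TraceModel("agonist", float(o), float(o) + 15.0, 5.0, 20.0)
                  for o in onsets]
        ts = make_trace_set(models, n_frames=120, baselines=1.0)
        df = analyze_traceset(ts, [ZONE], CFG)
        true_latency = onsets - ZONE.start
        assert np.all(np.abs(df["latency_s"].to_numpy() - true_latency) <= 1.0)

    def test_zone_outside_span_rejected(self):
        ts = make_trace_set([TraceModel("flat")], n_frames=50)
        with pytest.raises(ValueError, match="outside the trace"):
            analyze_traceset(ts, [StimulationZone(200, 300)], CFG)

    def test_overlapping_zones_rejected(self):
        ts = make_trace_set([TraceModel("flat")], n_frames=120)
        with pytest.raises(ValueError, match="non-overlapping"):
            analyze_traceset(
                ts, [StimulationZone(20, 60), StimulationZone(50, 80)], CFG)


class TestParseZones:
    def test_two_zone_string(self):
        zones = parse_zones("200:800,900:1074")
        assert zones[0] == StimulationZone(200, 800)
        assert zones[1] == StimulationZone(900, 1074)

    def test_invalid_zone_rejected(self):
        with pytest.raises(ValueError):
            parse_zones("100:50")
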