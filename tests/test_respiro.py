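import dataclasses

import numpy as np
import pandas as pd
import pytest

import respclim as rc
from respclim.respiro import (
    BaselinePair,
    CycleSet,
    DetectOpts,
    MeasureOpts,
    RespTrace,
    compute_fge,
    compute_vco2,
    detect_cycles,
    fit_baseline_drift,
    flow_to_stp,
    load_trace,
    trim_settling,
)


def make_constant_trace(ppm, flow=100.0, n=600):
    t = np.arange(n, dtype=float)
    return RespTrace(time=t, co2_ppm=np.full(n, float(ppm)), flow_rate_stp=flow)


def processed(params):
    """Simulate, split, drift-fit and trim one recording."""
    trace, truth = rc.simulate_trace(params)
    meas, baselines = rc.split_record(trace, truth)
    drift = fit_baseline_drift(baselines)
    trimmed = trim_settling(meas, params.settle_in, params.settle_out)
    return trimmed, drift, truth, meas, baselines


class TestFlowToStp:
    @pytest.mark.parametrize("args,expected", [
        ((100.0, 0.0, 101.3, 0.0), 100.0),          # identity at STP
        ((100.0, 25.0, 101.3, 0.0), 91.61496),      # 100*273.15/298.15
        ((100.0, 0.0, 101.3, 0.02), 98.0),          # water-vapour dilution
        ((100.0, 0.0, 50.65, 0.0), 50.0),           # half pressure
    ])
    def test_ideal_gas_arithmetic(self, args, expected):
        assert flow_to_stp(*args) == pytest.approx(expected, rel=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            flow_to_stp(100, 25, 101.3, 1.0)
        with pytest.raises(ValueError):
            flow_to_stp(100, 25, -1.0)


class TestBaselineDrift:
    def test_midpoint_of_line(self):
        pre = np.linspace(-60.0, 60.0, 121)     # centred at t=0
        post = np.linspace(3180.0, 3300.0, 121)  # centred at t=3240
        bl = BaselinePair(pre, np.full(121, 10.0), post, np.full(121, 12.0))
        drift = fit_baseline_drift(bl)
        assert drift.fi_of(1620.0) == pytest.approx(11.0e-6, rel=1e-9)

    def test_constant_baselines_give_zero_slope(self):
        bl = BaselinePair(np.arange(120.0), np.full(120, 8.5),
                          np.arange(3000.0, 3120.0), np.full(120, 8.5))
        drift = fit_baseline_drift(bl)
        assert drift.slope_ppm_per_s == pytest.approx(0.0, abs=1e-12)
        assert drift.fi_of(12345.0) == pytest.approx(8.5e-6)

    @pytest.mark.parametrize("slope_per_min", [0.5, 2.0, -1.0])
    def test_recovers_simulated_drift_slope(self, slope_per_min):
        p = rc.TraceSimParams(drift_slope=slope_per_min)
        trace, truth = rc.simulate_trace(p)
        _, baselines = rc.split_record(trace, truth)
        drift = fit_baseline_drift(baselines)
        assert drift.slope_ppm_per_s * 60 == pytest.approx(slope_per_min, rel=1e-6)

    def test_baseline_ordering_enforced(self):
        with pytest.raises(ValueError, match="after"):
            BaselinePair(np.arange(100.0, 200.0), np.zeros(100),
                         np.arange(50.0), np.zeros(50))


class TestTrimSettling:
    def test_hour_trace_leaves_40_minutes(self):
        trace = make_constant_trace(10.0, n=3601)
        out = trim_settling(trace, 600, 600)
        assert out.duration == pytest.approx(2400.0)
        assert out.time[0] == 600.0  # original timestamps preserved

    def test_zero_settling_is_identity(self):
        trace = make_constant_trace(10.0, n=100)
        out = trim_settling(trace, 0, 0)
        assert np.array_equal(out.time, trace.time)

    def test_short_trace_errors(self):
        with pytest.raises(ValueError, match="settling"):
            trim_settling(make_constant_trace(10.0, n=900), 600, 600)


class TestDetectCycles:
    def test_noiseless_burst_starts_within_two_samples(self):
        p = rc.TraceSimParams()
        trimmed, drift, truth, _, _ = processed(p)
        cyc = detect_cycles(trimmed, drift)
        true_starts = np.array([b[0] for b in truth.burst_bounds])
        for s, _ in cyc.bursts:
            assert np.min(np.abs(true_starts - s)) <= 2.0
        assert cyc.n_complete >= 7

    def test_flat_trace_flags_no_dgc(self):
        p = rc.TraceSimParams(true_vco2=0.0)
        trimmed, drift, *_ = processed(p)
        cyc = detect_cycles(trimmed, drift)
        assert cyc.n_complete == 0
        assert "no_dgc" in cyc.flags

    def test_noisy_cycle_count_matches_truth(self):
        # noise at ~5% of burst amplitude; period chosen so no burst sits
        # exactly on a window edge
        hits = 0
        for seed in range(20):
            p = rc.TraceSimParams(noise_sd=3.2, cycle_period=113.0, seed=seed)
            trimmed, drift, truth, _, _ = processed(p)
            cyc = detect_cycles(trimmed, drift)
            t0, t1 = trimmed.time[0], trimmed.time[-1]
            expected = len([b for b in truth.burst_bounds if t0 <= b[0] <= t1]) - 1
            hits += cyc.n_complete == expected
        assert hits >= 19

    def test_deterministic_for_fixed_opts(self):
        p = rc.TraceSimParams(noise_sd=2.0, seed=11)
        trimmed, drift, *_ = processed(p)
        c1 = detect_cycles(trimmed, drift)
        c2 = detect_cycles(trimmed, drift)
        assert c1.bursts == c2.bursts


class TestComputeVco2:
    def test_constant_signal_equals_closed_form(self):
        trace = make_constant_trace(50.0)
        drift = rc.DriftModel(intercept_ppm=10.0, slope_ppm_per_s=0.0)
        v = compute_vco2(trace, drift, (0, 599))
        expected = 100.0 * (50e-6 - 10e-6) / (1 - 50e-6)
        assert v == pytest.approx(expected, rel=1e-14)

    def test_fe_equal_fi_gives_zero(self):
        trace = make_constant_trace(10.0)
        drift = rc.DriftModel(intercept_ppm=10.0, slope_ppm_per_s=0.0)
        assert compute_vco2(trace, drift, (0, 599)) == pytest.approx(0.0, abs=1e-18)

    def test_whole_cycle_average_recovers_truth(self):
        p = rc.TraceSimParams(true_vco2=0.002)
        trimmed, drift, truth, _, _ = processed(p)
        cyc = detect_cycles(trimmed, drift)
        start = cyc.bursts[0][0]
        v = compute_vco2(trimmed, drift, (start, cyc.bursts[7][0]))
        assert v == pytest.approx(0.002, rel=5e-3)

    def test_window_start_invariance_across_cycle_boundaries(self):
        """Whole-cycle averages agree no matter which boundary starts the window."""
        p = rc.TraceSimParams()
        trimmed, drift, truth, _, _ = processed(p)
        cyc = detect_cycles(trimmed, drift)
        vals = [compute_vco2(trimmed, drift, (cyc.bursts[i][0], cyc.bursts[i + 7][0]))
                for i in range(4)]
        assert np.ptp(vals) / np.mean(vals) < 5e-3


class TestComputeFge:
    def test_seven_cycles_of_120s(self):
        bursts = [(120.0 * i, 120.0 * i + 36.0) for i in range(8)]
        cyc = CycleSet(bursts=bursts,
                       cycles=[(b[0], bursts[i + 1][0]) for i, b in enumerate(bursts[:-1])],
                       n_complete=7)
        fge, span = compute_fge(cyc, k=7)
        assert fge == 0.5
        assert span == 840.0

    def test_single_60s_cycle(self):
        bursts = [(0.0, 20.0), (60.0, 80.0)]
        cyc = CycleSet(bursts=bursts, cycles=[(0.0, 60.0)], n_complete=1)
        fge, _ = compute_fge(cyc, k=1)
        assert fge == 1.0

    def test_strict_mode_uses_last_burst_end(self):
        bursts = [(120.0 * i, 120.0 * i + 36.0) for i in range(8)]
        cyc = CycleSet(bursts=bursts, cycles=[], n_complete=7)
        fge, span = compute_fge(cyc, k=7, mode="first_to_last_burst_end")
        assert span == 6 * 120.0 + 36.0
        assert fge == pytest.approx(7 / (span / 60))

    def test_insufficient_cycles_raise(self):
        cyc = CycleSet(bursts=[(0.0, 10.0)], cycles=[], n_complete=0)
        with pytest.raises(ValueError, match="complete cycles"):
            compute_fge(cyc, k=7)

    def test_jittered_periods_give_exact_span_ratio(self):
        p = rc.TraceSimParams(cycle_jitter_sd=8.0, seed=4)
        trimmed, drift, truth, _, _ = processed(p)
        cyc = detect_cycles(trimmed, drift)
        fge, span = compute_fge(cyc, k=7)
        assert fge == pytest.approx(7 / (span / 60), rel=1e-12)
        true_starts = np.array([b[0] for b in truth.burst_bounds])
        det = np.array([b[0] for b in cyc.bursts[:8]])
        matched = [true_starts[np.argmin(np.abs(true_starts - d))] for d in det]
        assert span == pytest.approx(matched[7] - matched[0], abs=4.0)


class TestMeasureBee:
    def test_end_to_end_recovers_truth(self):
        p = rc.TraceSimParams(true_vco2=0.002, cycle_period=120.0)
        trace, truth = rc.simulate_trace(p)
        meas, baselines = rc.split_record(trace, truth)
        rec = rc.measure_bee(meas, baselines)
        assert rec.vco2_ml_min == pytest.approx(0.002, rel=5e-3)
        assert rec.fge_min == 0.5
        assert rec.n_cycles_used == 7
        assert "insufficient_cycles" not in rec.qc_flags

    def test_drift_invariance(self):
        """A linear analyser ramp on baseline+signal leaves V'CO2 unchanged."""
        recs = []
        for slope in (0.0, 2.0):
            p = rc.TraceSimParams(drift_slope=slope, seed=1)
            trace, truth = rc.simulate_trace(p)
            rec = rc.measure_bee(*rc.split_record(trace, truth))
            recs.append(rec.vco2_ml_min)
        assert recs[1] == pytest.approx(recs[0], rel=1e-3)

    def test_too_few_cycles_excluded_with_flag(self):
        # 700 s analysis window holds only ~5 full cycles of 120 s
        p = rc.TraceSimParams(duration=1900.0)
        trace, truth = rc.simulate_trace(p)
        rec = rc.measure_bee(*rc.split_record(trace, truth))
        assert "insufficient_cycles" in rec.qc_flags
        assert np.isnan(rec.vco2_ml_min)

    def test_opt_in_accepts_fewer_cycles(self):
        p = rc.TraceSimParams(duration=1900.0)
        trace, truth = rc.simulate_trace(p)
        opts = MeasureOpts(require_k=False)
        rec = rc.measure_bee(*rc.split_record(trace, truth), opts)
        assert "fewer_cycles_accepted" in rec.qc_flags
        assert 3 <= rec.n_cycles_used < 7
        assert rec.vco2_ml_min == pytest.approx(0.002, rel=0.01)

    def test_determinism(self):
        p = rc.TraceSimParams(noise_sd=2.0, seed=9)
        trace, truth = rc.simulate_trace(p)
        meas, baselines = rc.split_record(trace, truth)
        r1 = rc.measure_bee(meas, baselines)
        r2 = rc.measure_bee(meas, baselines)
        assert (r1.vco2_ml_min, r1.fge_min) == (r2.vco2_ml_min, r2.fge_min)


class TestLoadTrace:
    def test_roundtrip_through_csv(self, tmp_path, default_trace):
        trace, truth = default_trace
        csv = tmp_path / "bee1.csv"
        meta = rc.write_trace(trace, truth, csv)
        loaded, baselines = load_trace(csv, meta)
        meas, bl0 = rc.split_record(trace, truth)
        assert np.allclose(loaded.co2_ppm, meas.co2_ppm)
        assert np.allclose(baselines.pre_ppm, bl0.pre_ppm)
        rec = rc.measure_bee(loaded, baselines)
        assert rec.vco2_ml_min == pytest.approx(0.002, rel=5e-3)

    def test_shuffled_timestamps_error_names_row(self, tmp_path):
        csv = tmp_path / "bad.csv"
        pd.DataFrame({"time_s": [0.0, 2.0, 1.0, 3.0], "co2_ppm": [1, 2, 3, 4]}).to_csv(
            csv, index=False)
        meta = {"flow_rate_stp": 100.0, "baseline_pre": [0, 1],
                "baseline_post": [2, 3], "measurement": [1, 2]}
        with pytest.raises(ValueError, match="row 2"):
            load_trace(csv, meta)

    def test_gap_over_5s_flagged(self, tmp_path):
        t = np.concatenate([np.arange(200.0), np.arange(210.0, 400.0)])
        csv = tmp_path / "gap.csv"
        pd.DataFrame({"time_s": t, "co2_ppm": np.full(t.size, 10.0)}).to_csv(
            csv, index=False)
        meta = {"flow_rate_stp": 100.0, "baseline_pre": [0, 50],
                "baseline_post": [350, 399], "measurement": [50, 350]}
        trace, _ = load_trace(csv, meta)
        assert "gap" in trace.qc_flags

    def test_multichannel_import(self, tmp_path):
        path = tmp_path / "wide.tsv"
        pd.DataFrame({"time_s": [0.0, 1.0], "ch1": [10.0, 11.0],
                      "ch2": [12.0, 13.0]}).to_csv(path, sep="\t", index=False)
        chans = rc.load_multichannel(path)
        assert set(chans) == {"ch1", "ch2"}
        assert list(chans["ch1"]["co2_ppm"]) == [10.0, 11.0]
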