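"""Event-sorting cascade: derivative, gates, conductances, intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swimsort import (
    CellSimConfig,
    DetectionThresholds,
    GTEvent,
    TraceRecording,
    TrialProtocol,
    derivative,
    detect_complex_spikes,
    detect_events,
    detect_hyperpolarizations,
    detect_long_depolarizations,
    detect_pfepsps,
    detect_simple_spikes,
    distribution_overlap,
    estimate_conductance,
    normalize_conductances,
    simulate_trace,
)
from swimsort.events import events_to_table

FS = 10_000.0


def _trace(values, fs=FS, cap=10.7):
    return TraceRecording(np.asarray(values, float), fs, capacitance=cap)


class TestDerivative:
    def test_linear_ramp_constant_slope(self):
        t = np.arange(0, 0.1, 1 / FS)
        tr = _trace(5.0 * t * 1000.0)  # 5 mV/ms
        d = derivative(tr, 0.2)
        np.testing.assert_allclose(d, 5.0, rtol=1e-9)

    def test_current_step_on_passive_cell(self):
        # -250 pA / 10 pF -> -25 mV/ms measured from the simulated sweep
        cfg = CellSimConfig(basal_complex_rate=0, basal_simple_rate=0,
                            basal_pf_rate=0, noise_sd=0.0, capacitance=10.0,
                            leak_conductance=1e-12, offset_current=-250.0)
        proto = TrialProtocol(1, "us_alone", us_time=0.05, sweep_duration=0.1)
        tr, _ = simulate_trace(cfg, proto, seed=0)
        d = derivative(tr, 0.2)
        assert np.median(d[5:-5]) == pytest.approx(-25.0, rel=1e-6)

    def test_white_noise_slope_sd_matches_regression_formula(self):
        # var(slope) = 12 s^2 / (n (n^2-1) dt^2) for an n-point regression
        rng = np.random.default_rng(0)
        sigma = 0.2
        tr = _trace(rng.normal(0, sigma, 200_000))
        d = derivative(tr, 0.2)[100:-100]
        n, dt_ms = 3, 1000.0 / FS
        expected_sd = np.sqrt(12 * sigma ** 2 / (n * (n * n - 1) * dt_ms ** 2))
        assert np.std(d) == pytest.approx(expected_sd, rel=0.02)

    def test_window_too_short_rejected(self):
        tr = _trace(np.zeros(100))
        with pytest.raises(ValueError, match="3 samples"):
            derivative(tr, 0.05)

    def test_requires_current_clamp(self):
        vr = TraceRecording(np.zeros(100), FS, modality="ventral_root")
        with pytest.raises(ValueError, match="current-clamp"):
            derivative(vr)


class TestEstimateConductance:
    def test_unit_arithmetic(self):
        # 10 pF x 25 mV/ms at -60 mV toward 0 mV: 250/60 ~ 4.17 nS
        g, reliable = estimate_conductance(25.0, -60.0, 10.0, 0.0)
        assert g == pytest.approx(250.0 / 60.0)
        assert reliable

    def test_simple_spike_worked_example(self):
        # 10.5 mV/ms at -30 mV on 10.7 pF toward +55 -> ~1.32 nS, ~ -112 pA
        g, _ = estimate_conductance(10.5, -30.0, 10.7, 55.0)
        assert g == pytest.approx(1.32, abs=0.01)
        assert g * (-30.0 - 55.0) == pytest.approx(-112.35, abs=0.1)

    def test_small_driving_force_flagged(self):
        g, reliable = estimate_conductance(5.0, -5.0, 10.0, 0.0)
        assert not reliable
        assert np.isfinite(g)

    def test_missing_capacitance_rejected(self):
        with pytest.raises(ValueError, match="capacitance"):
            estimate_conductance(10.0, -60.0, None, 0.0)


class TestComplexSpikes:
    def test_single_cf_event_recovered(self, single_cf_trace):
        trace, truth = single_cf_trace
        events, _ = detect_complex_spikes(trace)
        assert len(events) == 1
        assert events[0].time == pytest.approx(truth[0].time, abs=5e-4)
        assert events[0].baseline_rise_flag

    def test_conductance_estimate_within_15_percent(self, single_cf_trace):
        trace, truth = single_cf_trace
        (ev,), _ = detect_complex_spikes(trace)
        assert ev.conductance == pytest.approx(truth[0].conductance, rel=0.15)

    def test_flat_trace_yields_nothing(self, quiet_cell, short_protocol):
        trace, _ = simulate_trace(quiet_cell, short_protocol, seed=0)
        events, _ = detect_complex_spikes(trace)
        assert events == []

    def test_three_events_none_split(self, noisy_quiet_cell):
        proto = TrialProtocol(1, "us_alone", us_time=2.5, sweep_duration=3.0)
        extra = [GTEvent(t, "complex", None) for t in (0.5, 1.2, 2.0)]
        trace, truth = simulate_trace(noisy_quiet_cell, proto, seed=2,
                                      extra_events=extra)
        events, _ = detect_complex_spikes(trace)
        assert len(events) == 3

    def test_missing_capacitance_rejected(self, single_cf_trace):
        trace, _ = single_cf_trace
        trace2 = TraceRecording(trace.values, trace.sampling_rate)
        trace2.capacitance = None
        with pytest.raises(ValueError, match="capacitance"):
            detect_complex_spikes(trace2)


class TestSimpleSpikes:
    def test_ten_inserted_spikes_recovered(self, noisy_quiet_cell):
        proto = TrialProtocol(1, "us_alone", us_time=0.95, sweep_duration=1.0)
        extra = [GTEvent(0.1 + 0.08 * i, "simple", None) for i in range(10)]
        trace, truth = simulate_trace(noisy_quiet_cell, proto, seed=2,
                                      extra_events=extra)
        cxs, _ = detect_complex_spikes(trace)
        ss = detect_simple_spikes(trace, cxs)
        assert len(cxs) == 0
        assert len(ss) >= 9
        assert all(e.inflection_flag for e in ss)

    def test_cf_only_sweep_has_no_simple_events(self, single_cf_trace):
        trace, _ = single_cf_trace
        cxs, _ = detect_complex_spikes(trace)
        assert detect_simple_spikes(trace, cxs) == []

    def test_depolarized_cell_pf_only(self):
        """A cell too depolarized to spike still shows detectable pfEPSPs."""
        cfg = CellSimConfig(basal_complex_rate=0, basal_simple_rate=0,
                            basal_pf_rate=0, noise_sd=0.1,
                            resting_potential=-40.0, leak_reversal=-40.0)
        proto = TrialProtocol(1, "us_alone", us_time=1.9, sweep_duration=2.0)
        extra = [GTEvent(0.4 + 0.3 * i, "pfEPSP", 0.25) for i in range(5)]
        trace, _ = simulate_trace(cfg, proto, seed=3, extra_events=extra)
        det = detect_events(trace)
        assert det["simple"] == []
        assert len(det["pfEPSP"]) >= 3


class TestPfEpsps:
    def test_single_event_current_near_minus_10_pa(self):
        cfg = CellSimConfig(basal_complex_rate=0, basal_simple_rate=0,
                            basal_pf_rate=0, noise_sd=0.05)
        proto = TrialProtocol(1, "us_alone", us_time=0.95, sweep_duration=1.0)
        trace, _ = simulate_trace(cfg, proto, seed=3,
                                  extra_events=[GTEvent(0.5, "pfEPSP", 0.17)])
        events = detect_pfepsps(trace, [])
        assert len(events) == 1
        current = events[0].conductance * (-60.0 - 0.0)
        assert current == pytest.approx(-10.2, rel=0.35)

    def test_noise_only_trace_no_events(self, noisy_quiet_cell):
        proto = TrialProtocol(1, "us_alone", us_time=4.5, sweep_duration=5.0)
        n_total = 0
        for seed in range(10):
            trace, _ = simulate_trace(noisy_quiet_cell, proto, seed=seed)
            n_total += len(detect_pfepsps(trace, []))
        assert n_total == 0  # stringency bias: no false positives on noise

    def test_summating_train_majority_recovered(self, noisy_quiet_cell):
        proto = TrialProtocol(1, "us_alone", us_time=2.5, sweep_duration=3.0)
        extra = [GTEvent(1.0 + 0.02 * i, "pfEPSP", None) for i in range(20)]
        trace, truth = simulate_trace(noisy_quiet_cell, proto, seed=4,
                                      extra_events=extra)
        events = detect_pfepsps(trace, [])
        assert len(events) >= 12  # >= 60%; undercounting during summation OK


class TestCascadeExclusivity:
    def test_no_sample_shares_two_labels(self):
        cfg = CellSimConfig()
        proto = TrialProtocol(1, "us_alone", us_time=7.5, sweep_duration=8.0)
        trace, _ = simulate_trace(cfg, proto, seed=9)
        det = detect_events(trace)
        times = []
        for lab in ("complex", "simple", "pfEPSP"):
            times += [(e.time, lab) for e in det[lab]]
        times.sort()
        for (t1, l1), (t2, l2) in zip(times, times[1:]):
            assert t2 - t1 > 0.002 or l1 == l2

    def test_complex_set_invariant_to_simple_threshold(self):
        cfg = CellSimConfig()
        proto = TrialProtocol(1, "us_alone", us_time=7.5, sweep_duration=8.0)
        trace, _ = simulate_trace(cfg, proto, seed=10)
        a, _ = detect_complex_spikes(trace, DetectionThresholds())
        b, _ = detect_complex_spikes(trace, DetectionThresholds(theta_simple=5.0))
        assert [e.time for e in a] == [e.time for e in b]


class TestNormalization:
    def _table(self):
        det = {"complex": [], "simple": [], "pfEPSP": []}
        import pandas as pd
        return pd.DataFrame({
            "cell_id": ["c"] * 3,
            "trial_index": [1] * 3,
            "time_s": [0.1, 0.2, 0.3],
            "label": ["complex", "complex", "simple"],
            "peak_dvdt_mv_per_ms": [25.0, 30.0, 10.0],
            "conductance_ns": [4.0, 6.0, 1.0],
            "normalized_conductance": [np.nan] * 3,
            "in_cs_window": [False] * 3,
            "in_illumination": [False] * 3,
        })

    def test_mean_complex_normalized_is_one(self):
        df, skipped = normalize_conductances(self._table())
        cxs = df[df["label"] == "complex"]["normalized_conductance"]
        np.testing.assert_allclose(sorted(cxs), [0.8, 1.2])
        assert cxs.mean() == pytest.approx(1.0)
        assert skipped == []

    def test_simple_events_normalized_by_complex_mean(self):
        df, _ = normalize_conductances(self._table())
        ss = df[df["label"] == "simple"]["normalized_conductance"]
        assert ss.iloc[0] == pytest.approx(0.2)

    def test_cell_without_complex_is_skipped(self):
        t = self._table()
        t["label"] = "simple"
        df, skipped = normalize_conductances(t)
        assert skipped == ["c"]
        assert df["normalized_conductance"].isna().all()


class TestDistributionOverlap:
    def test_hand_computed_min_sum(self):
        # bins [1,2),[2,3),[3,4): p=(2/3,1/3,0), q=(0,1/3,2/3) -> 33.3%
        val = distribution_overlap([1, 1, 2], [2, 3, 3], 1.0)
        assert val == pytest.approx(100.0 / 3.0)

    def test_identical_samples_full_overlap(self):
        a = [0.5, 1.5, 2.5, 2.5]
        assert distribution_overlap(a, a, 0.2) == pytest.approx(100.0)

    def test_disjoint_supports_zero(self):
        assert distribution_overlap([1, 2], [10, 11], 0.5) == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            distribution_overlap([], [1.0], 0.1)

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            distribution_overlap([1.0], [1.0], 0.0)

    @given(st.lists(st.floats(0.01, 50.0), min_size=1, max_size=50),
           st.lists(st.floats(0.01, 50.0), min_size=1, max_size=50),
           st.floats(0.05, 2.0))
    @settings(max_examples=60, deadline=None)
    def test_symmetric_and_bounded(self, a, b, bw):
        x = distribution_overlap(a, b, bw)
        y = distribution_overlap(b, a, bw)
        assert x == pytest.approx(y, abs=1e-9)
        assert -1e-9 <= x <= 100.0 + 1e-9

    @given(st.lists(st.floats(0.1, 20.0), min_size=2, max_size=30),
           st.lists(st.floats(0.1, 20.0), min_size=2, max_size=30),
           st.floats(0.1, 1.0), st.floats(0.5, 4.0))
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_common_rescaling(self, a, b, bw, scale):
        x = distribution_overlap(a, b, bw)
        y = distribution_overlap([v * scale for v in a],
                                 [v * scale for v in b], bw * scale)
        assert x == pytest.approx(y, abs=1e-6)


class TestLongDepolarizations:
    def _barrage_trace(self, seed=4, n=20, start=1.0, interval=0.02):
        cfg = CellSimConfig(basal_complex_rate=0, basal_simple_rate=0,
                            basal_pf_rate=0, noise_sd=0.2)
        proto = TrialProtocol(1, "us_alone", us_time=2.5, sweep_duration=3.0)
        extra = [GTEvent(start + interval * i, "pfEPSP", None)
                 for i in range(n)]
        return simulate_trace(cfg, proto, seed=seed, extra_events=extra)

    def test_barrage_yields_one_interval_with_pf_onset(self):
        trace, truth = self._barrage_trace()
        det = detect_events(trace)
        ivs = detect_long_depolarizations(trace, det["pfEPSP"],
                                          baseline_window=(0.0, 0.9))
        assert len(ivs) == 1
        assert ivs[0].onset == pytest.approx(1.0, abs=0.02)
        assert ivs[0].duration >= 0.2
        assert not ivs[0].baseline_from_default_window

    def test_isolated_pf_makes_no_interval(self):
        trace, _ = self._barrage_trace(n=1)
        det = detect_events(trace)
        assert detect_long_depolarizations(
            trace, det["pfEPSP"], baseline_window=(0.0, 0.9)) == []

    def test_duration_boundary_inclusive(self):
        # a synthetic square bump: exactly 200 ms passes, 199 ms does not
        fs = FS
        for ms, expected in ((230, 1), (170, 0)):
            v = np.full(int(fs * 2), -60.0)
            i0 = int(0.8 * fs)
            v[i0:i0 + int(ms / 1000 * fs)] += 5.0
            # 20 ms median filtering erodes ~15 ms off each edge of a square
            tr = _trace(v)
            ivs = detect_long_depolarizations(tr, [], baseline_window=(0, 0.5))
            assert len(ivs) == expected, ms

    def test_default_baseline_is_flagged(self):
        trace, _ = self._barrage_trace()
        det = detect_events(trace)
        ivs = detect_long_depolarizations(trace, det["pfEPSP"])
        assert all(iv.baseline_from_default_window for iv in ivs)


class TestHyperpolarizations:
    def test_inhibitory_envelope_detected_with_trough(self, noisy_quiet_cell):
        proto = TrialProtocol(1, "us_alone", us_time=2.5, sweep_duration=3.0)
        trace, _ = simulate_trace(noisy_quiet_cell, proto, seed=5,
                                  inh_envelopes=[(1.2, 0.8)])
        ivs = detect_hyperpolarizations(trace, (0.0, 1.0))
        assert len(ivs) == 1
        assert ivs[0].trough == pytest.approx(-68.0, abs=1.5)

    def test_flat_trace_none(self, quiet_cell):
        proto = TrialProtocol(1, "us_alone", us_time=1.5, sweep_duration=2.0)
        trace, _ = simulate_trace(quiet_cell, proto, seed=0)
        assert detect_hyperpolarizations(trace, (0.0, 0.5)) == []

    def test_noise_only_none_across_seeds(self, noisy_quiet_cell):
        proto = TrialProtocol(1, "us_alone", us_time=1.5, sweep_duration=2.0)
        n = 0
        for seed in range(30):
            trace, _ = simulate_trace(noisy_quiet_cell, proto, seed=seed)
            n += len(detect_hyperpolarizations(trace, (0.0, 0.5)))
        assert n == 0

    def test_short_pretrial_rejected(self, quiet_cell):
        proto = TrialProtocol(1, "us_alone", us_time=1.5, sweep_duration=2.0)
        trace, _ = simulate_trace(quiet_cell, proto, seed=0)
        with pytest.raises(ValueError, match="200 ms"):
            detect_hyperpolarizations(trace, (0.0, 0.1))


def test_events_to_table_flags_cs_and_illumination(single_cf_trace):
    trace, _ = single_cf_trace
    det = detect_events(trace)
    proto = TrialProtocol(1, "paired", 0.4, 0.7, 0.7, (0.3, 0.8), 1.0)
    df = events_to_table(det, cell_id="c", trial_index=1, protocol=proto)
    assert df["in_cs_window"].all()
    assert df["in_illumination"].all()
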