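"""Cell classification and the latency/count statistics around CRs."""

import numpy as np
import pandas as pd
import pytest

from swimsort import (
    TrialOutcome,
    TrialProtocol,
    classify_cell,
    cs_window_counts,
    cxs_probability_near_cr,
    depolarization_latency,
    latency_stats,
    pf_count_during_cs,
)
from swimsort.classify import stratify_counts
from swimsort.events import DepolarizationInterval


def _events(rows):
    return pd.DataFrame(rows, columns=["cell_id", "trial_index", "time_s",
                                       "label"]).assign(
        peak_dvdt_mv_per_ms=20.0, conductance_ns=4.0,
        normalized_conductance=np.nan, in_cs_window=False,
        in_illumination=False)


def _cr_outcome(idx, onset=3.0, offset=3.3):
    return TrialOutcome(idx, "paired", cr_present=True, cr_onset=onset,
                        cr_offset=offset)


def _protocol(n=3):
    return [TrialProtocol(i + 1, "paired", 2.0, 4.0, 4.0, None, 6.0)
            for i in range(n)]


class TestClassifyCell:
    def test_multiple_complex_spikes_is_mcs(self):
        rows = [("c", t, x, "complex") for t in (1, 2, 3)
                for x in (3.0, 3.1, 3.2)][:9]
        counts = {1: 3, 2: 3, 3: 3}
        ev = _events([("c", t, 3.0 + 0.1 * k, "complex")
                      for t, n in counts.items() for k in range(n)])
        res = classify_cell(ev, [_cr_outcome(i) for i in (1, 2, 3)],
                            _protocol())
        assert res.label == "MCS"
        assert res.per_cr_trial_cxs_counts == [3, 3, 3]

    def test_single_spike_most_trials_is_scs(self):
        counts = {1: 1, 2: 1, 3: 0, 4: 1}
        ev = _events([("c", t, 3.0, "complex")
                      for t, n in counts.items() if n])
        res = classify_cell(ev, [_cr_outcome(i) for i in (1, 2, 3, 4)],
                            _protocol(4))
        assert res.label == "SCS"

    def test_zero_on_all_cr_trials_is_zcs_despite_us_spikes(self):
        ev = _events([("c", t, 4.05, "complex") for t in (1, 2, 3)])
        res = classify_cell(ev, [_cr_outcome(i) for i in (1, 2, 3)],
                            _protocol())
        assert res.label == "ZCS"
        assert res.fraction_us_trials_with_cxs == pytest.approx(1.0)

    def test_tie_on_majority_resolves_to_scs(self):
        counts = {1: 2, 2: 1, 3: 2, 4: 1}
        ev = _events([("c", t, 3.0 + 0.05 * k, "complex")
                      for t, n in counts.items() for k in range(n)])
        res = classify_cell(ev, [_cr_outcome(i) for i in (1, 2, 3, 4)],
                            _protocol(4))
        assert res.label == "SCS"

    def test_padded_window_includes_leading_and_trailing_spikes(self):
        # one spike 74 ms before onset, one 223 ms after offset
        ev = _events([("c", 1, 3.0 - 0.074, "complex"),
                      ("c", 1, 3.3 + 0.223, "complex")])
        res = classify_cell(ev, [_cr_outcome(1)], _protocol(1))
        assert res.per_cr_trial_cxs_counts == [2]

    def test_no_cr_trials_rejected(self):
        with pytest.raises(ValueError, match="CR"):
            classify_cell(_events([]), [TrialOutcome(1, "paired")], _protocol(1))


class TestLatencyStats:
    def test_constant_latencies_zero_cv(self):
        s = latency_stats({1: [2.1], 2: [2.1]}, {1: 2.0, 2: 2.0})
        assert s.mean == pytest.approx(0.1)
        assert s.cv == pytest.approx(0.0)

    def test_hand_computed_cv(self):
        s = latency_stats({1: [2.05], 2: [2.15]}, {1: 2.0, 2: 2.0})
        # latencies 50 and 150 ms: SD/mean = 70.7/100
        assert s.cv == pytest.approx(0.7071, abs=1e-3)

    def test_near_zero_mean_flagged_undefined(self):
        s = latency_stats({1: [2.003], 2: [1.997]}, {1: 2.0, 2: 2.0},
                          nearest=True)
        assert s.cv is None and not s.defined

    def test_nearest_mode_allows_negative_latency(self):
        s = latency_stats({1: [1.93], 2: [1.92]}, {1: 2.0, 2: 2.0},
                          nearest=True)
        assert s.mean == pytest.approx(-0.075)

    def test_cv_scale_invariant_under_time_units(self):
        lat_s = latency_stats({1: [2.05], 2: [2.15]}, {1: 2.0, 2: 2.0})
        lat_ms = latency_stats({1: [2050.0], 2: [2150.0]},
                               {1: 2000.0, 2: 2000.0})
        assert lat_s.cv == pytest.approx(lat_ms.cv)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            latency_stats({1: [2.1]}, {1: 2.0})

    def test_scs_cohort_latency_recovery(self):
        """Programmed -74 +- 30 ms onset-locked latencies are recovered."""
        rng = np.random.default_rng(0)
        times, refs = {}, {}
        for t in range(1, 61):
            refs[t] = 3.0
            times[t] = [3.0 - 0.074 + rng.normal(0, 0.030)]
        s = latency_stats(times, refs, reference="cr_onset", nearest=True)
        assert s.mean == pytest.approx(-0.074, abs=3 * 0.030 / np.sqrt(60))


class TestWindowCounts:
    def test_empty_table_all_zero(self):
        df = cs_window_counts(_events([]), _protocol(3), align_trial=2)
        assert list(df["count"]) == [0, 0, 0]
        assert list(df["relative_trial"]) == [-1, 0, 1]

    def test_only_first_500ms_counted(self):
        ev = _events([("c", 1, 2.2, "complex"), ("c", 1, 2.7, "complex")])
        df = cs_window_counts(ev, _protocol(1))
        assert list(df["count"]) == [1]

    def test_pf_counts_span_whole_cs(self):
        ev = _events([("c", 1, 2.2, "pfEPSP"), ("c", 1, 3.7, "pfEPSP"),
                      ("c", 1, 4.5, "pfEPSP")])
        df = pf_count_during_cs(ev, _protocol(1))
        assert list(df["count"]) == [2]

    def test_stratified_triplets_exclude_cr_trials(self):
        proto = _protocol(9)
        ev = _events([("c", t, 2.1, "complex") for t in range(1, 10)])
        counts = cs_window_counts(ev, proto)
        outcomes = [TrialOutcome(i, "paired", cr_present=(i == 5))
                    for i in range(1, 10)]
        strata = stratify_counts(counts, outcomes, n_per_stratum=3)
        assert strata["early"] == pytest.approx(1.0)
        assert strata["late"] == pytest.approx(1.0)


class TestCxsProbabilityNearCr:
    def _crs(self):
        return pd.DataFrame([
            {"cell_id": "c", "trial_index": 1, "ordinal": 1,
             "onset": 3.0, "offset": 3.3},
            {"cell_id": "c", "trial_index": 2, "ordinal": 2,
             "onset": 3.1, "offset": 3.4},
        ])

    def test_no_events_zero_probabilities(self):
        df = cxs_probability_near_cr(_events([]), self._crs())
        assert list(df["p_onset"]) == [0, 0]
        assert list(df["p_offset"]) == [0, 0]

    def test_event_exactly_at_onset_counts_for_onset(self):
        ev = _events([("c", 1, 3.0, "complex")])
        df = cxs_probability_near_cr(ev, self._crs())
        assert df.loc[df["ordinal"] == 1, "p_onset"].iloc[0] == 1.0

    def test_onset_window_takes_precedence(self):
        # event within both windows (short CR) is counted once, at onset
        crs = pd.DataFrame([{"cell_id": "c", "trial_index": 1, "ordinal": 1,
                             "onset": 3.0, "offset": 3.05}])
        ev = _events([("c", 1, 3.2, "complex")])
        df = cxs_probability_near_cr(ev, crs)
        assert df["p_onset"].iloc[0] == 1.0
        assert df["p_offset"].iloc[0] == 0.0

    def test_offset_window_excludes_boundary_start(self):
        ev = _events([("c", 1, 3.5, "complex")])  # offset + 0.2
        df = cxs_probability_near_cr(ev, self._crs())
        assert df.loc[df["ordinal"] == 1, "p_offset"].iloc[0] == 1.0


class TestDepolarizationLatency:
    def test_worked_lag(self):
        iv = DepolarizationInterval(onset=2.829, offset=3.3,
                                    mean_depolarization=4.0)
        eps = [type("E", (), {"onset": 3.0})()]
        lags = depolarization_latency([iv], eps)
        assert lags == [pytest.approx(-0.171)]

    def test_coincident_onsets_zero(self):
        iv = DepolarizationInterval(onset=3.0, offset=3.4,
                                    mean_depolarization=4.0)
        eps = [type("E", (), {"onset": 3.0})()]
        assert depolarization_latency([iv], eps) == [0.0]

    def test_far_intervals_skipped(self):
        iv = DepolarizationInterval(onset=0.5, offset=0.9,
                                    mean_depolarization=4.0)
        eps = [type("E", (), {"onset": 3.0})()]
        assert depolarization_latency([iv], eps) == []
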