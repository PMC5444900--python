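"""Trial scoring, learner criterion, acquisition and extinction logic."""

import numpy as np
import pytest

from swimsort import (
    LearnerModel,
    SwimEpisode,
    TrialOutcome,
    TrialProtocol,
    acquisition_trial,
    behavior_model,
    classify_trial,
    cr_trajectory,
    extinction_trials,
    learner_flag,
    summarize_session,
)
from swimsort.behavior import _cr_flags


def _episode(onset, n=7, freq=23.0, kind="unassigned"):
    times = [onset + i / freq for i in range(n)]
    return SwimEpisode(times[0], times[-1], times, kind)


def _paired(idx=1):
    return TrialProtocol(idx, "paired", 2.0, 4.0, 4.0, None, 6.0)


def _outcomes(flags, kind="paired"):
    return [TrialOutcome(i + 1, kind, cr_present=bool(f))
            for i, f in enumerate(flags)]


class TestClassifyTrial:
    def test_cr_with_latency(self):
        out = classify_trial([_episode(3.1)], _paired())
        assert out.cr_present and not out.ur_present
        assert out.cr_metrics[0] == pytest.approx(1.1)
        assert out.cr_metrics[1] == 7

    def test_ur_only(self):
        out = classify_trial([_episode(4.017)], _paired())
        assert out.ur_present and not out.cr_present
        assert out.ur_onset == pytest.approx(4.017)

    def test_spontaneous_episode_outside_windows(self):
        out = classify_trial([_episode(0.5)], _paired())
        assert not out.cr_present and not out.ur_present
        assert out.spontaneous_episodes == 1

    def test_episode_never_both_cr_and_ur(self):
        eps = [_episode(3.0), _episode(4.02)]
        out = classify_trial(eps, _paired())
        assert out.cr_present and out.ur_present
        assert {e.kind for e in eps} == {"CR", "UR"}

    def test_cr_window_half_open_at_us(self):
        out = classify_trial([_episode(4.0)], _paired())
        assert not out.cr_present  # onset exactly at the US is not a CR
        assert out.ur_present

    def test_cs_alone_offset_response_counts(self):
        trial = TrialProtocol(1, "cs_alone", 2.0, 4.0, None, None, 6.0)
        out = classify_trial([_episode(4.1)], trial)
        assert out.cr_present


class TestLearnerFlag:
    def test_strict_inequality_at_criterion(self):
        assert not learner_flag(_outcomes([1] * 14 + [0] * 56))  # 20% exactly
        assert learner_flag(_outcomes([1] * 15 + [0] * 55))

    def test_learner_example(self):
        assert learner_flag(_outcomes([1] * 31 + [0] * 39))  # 44.3%

    def test_no_cs_trials_rejected(self):
        with pytest.raises(ValueError):
            learner_flag(_outcomes([1, 0], kind="us_alone"))


class TestAcquisition:
    @pytest.mark.parametrize("flags,expected", [
        ([0, 0, 1, 1, 0], 3),
        ([1, 0, 1, 0], None),
        ([1, 1, 0, 0], 1),
        ([0, 0, 0], None),
    ])
    def test_first_consecutive_run(self, flags, expected):
        assert acquisition_trial(_outcomes(flags)) == expected

    def test_monte_carlo_recovery_of_programmed_change_point(self):
        """Median detected acquisition within +-3 of the programmed trial."""
        model = LearnerModel(acquisition_trial=28, plateau_cr_prob=0.6)
        protocol = [_paired(i + 1) for i in range(70)]
        detected = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            outs = []
            n_crs = 0
            for p in protocol:
                plan = behavior_model(model, p, rng, n_prior_crs=n_crs)
                n_crs += plan.cr
                outs.append(TrialOutcome(p.trial_index, "paired",
                                         cr_present=plan.cr))
            a = acquisition_trial(outs)
            if a is not None:
                detected.append(a)
        assert len(detected) >= 190
        assert abs(np.median(detected) - 28) <= 3


class TestExtinction:
    def test_worked_examples(self):
        assert extinction_trials(_outcomes([1, 1, 0, 0, 0], "cs_alone")) == 2
        assert extinction_trials(_outcomes([0, 0, 0], "cs_alone")) == 0
        assert extinction_trials(_outcomes([1, 0, 1, 0], "cs_alone")) is None

    def test_no_cs_alone_phase_rejected(self):
        with pytest.raises(ValueError):
            extinction_trials(_outcomes([1, 0, 0]))

    def test_cohort_median_matches_independent_decay_oracle(self):
        """Trials-to-extinction under p_k = plateau * decay^k matches a
        direct binomial simulation of the same process."""
        model = LearnerModel(acquisition_trial=1, plateau_cr_prob=0.59,
                             extinction_decay=0.5)
        trial = lambda i: TrialProtocol(i, "cs_alone", 2.0, 4.0, None, None, 6.0)

        def run_model(seed):
            rng = np.random.default_rng(seed)
            outs = []
            streak = 0
            for i in range(1, 16):
                plan = behavior_model(model, trial(i + 30), rng,
                                      cs_alone_streak=streak)
                streak += 1
                outs.append(TrialOutcome(i, "cs_alone", cr_present=plan.cr))
            return extinction_trials(outs)

        def run_oracle(seed):
            rng = np.random.default_rng(seed)
            flags = [rng.uniform() < 0.59 * 0.5 ** k for k in range(15)]
            run = 0
            for i, f in enumerate(flags):
                run = 0 if f else run + 1
                if run >= 3:
                    return i - 2
            return None

        a = [run_model(s) for s in range(300)]
        b = [run_oracle(s + 1000) for s in range(300)]
        med_a = np.median([x for x in a if x is not None])
        med_b = np.median([x for x in b if x is not None])
        assert med_a == med_b


class TestTrajectoryAndSummary:
    def test_trajectory_lengths(self):
        outs = _outcomes([1, 0, 1])
        outs[0].cr_metrics = (1.2, 7, 23.0)
        outs[2].cr_metrics = (0.9, 9, 25.0)
        traj = cr_trajectory(outs)
        assert len(traj) == 2
        assert cr_trajectory(_outcomes([0, 0])) == []

    def test_cohort_latency_decreases_and_bursts_increase(self):
        model = LearnerModel(acquisition_trial=5)
        protocol = [_paired(i + 1) for i in range(40)]
        first, fifth = [], []
        for seed in range(150):
            rng = np.random.default_rng(seed)
            outs = []
            n_crs = 0
            for p in protocol:
                plan = behavior_model(model, p, rng, n_prior_crs=n_crs)
                n_crs += plan.cr
                o = TrialOutcome(p.trial_index, "paired", cr_present=plan.cr)
                if plan.cr:
                    o.cr_metrics = (plan.cr_onset - p.cs_onset,
                                    plan.cr_n_bursts, plan.cr_burst_freq)
                outs.append(o)
            traj = cr_trajectory(outs)
            if len(traj) >= 5:
                first.append(traj[0])
                fifth.append(traj[4])
        assert np.mean([t[0] for t in fifth]) < np.mean([t[0] for t in first])
        assert np.mean([t[1] for t in fifth]) > np.mean([t[1] for t in first])

    def test_summary_percentages_consistent_and_round_trip(self):
        outs = _outcomes([0, 1, 1, 0, 1, 0, 0, 0, 1, 0, 1, 1])
        s = summarize_session(outs, block_size=6)
        assert s.cr_percent == pytest.approx(100 * 6 / 12)
        assert s.block_cr_percent == [pytest.approx(50.0),
                                      pytest.approx(50.0)]
        # recompute from the serialized form
        d = s.to_dict()
        flags = _cr_flags(outs)
        assert d["cr_percent"] == pytest.approx(100 * sum(flags) / len(flags))
        assert d["learner"] == (s.cr_percent > 20.0)


def test_learner_prevalence_monotone_in_programmed_probability():
    """Raising the programmed CR probability never lowers flag prevalence."""
    protocol = [_paired(i + 1) for i in range(40)]
    rates = []
    for plateau in (0.15, 0.35, 0.6):
        model = LearnerModel(acquisition_trial=10, plateau_cr_prob=plateau)
        n_flag = 0
        for seed in range(150):
            rng = np.random.default_rng(seed)
            outs = []
            n_crs = 0
            for p in protocol:
                plan = behavior_model(model, p, rng, n_prior_crs=n_crs)
                n_crs += plan.cr
                outs.append(TrialOutcome(p.trial_index, "paired",
                                         cr_present=plan.cr))
            n_flag += learner_flag(outs)
        rates.append(n_flag / 150)
    assert rates[0] <= rates[1] <= rates[2]
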