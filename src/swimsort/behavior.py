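"""Behavioral scoring: CR/UR trial classification and session statistics.

A conditional response (CR) is a swim episode starting inside the CS
window, before the US; the unconditional response (UR) starts within a
short window after the US.  Windows are half-open [start, end).  A fish is
a "learner" when it produces CRs on strictly more than 20% of CS-bearing
trials; "acquisition" is the first trial of the earliest run of
consecutive CR trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .swim import SwimEpisode
from .synthetic import TrialProtocol


@dataclass
class TrialOutcome:
    trial_index: int
    kind: str = "paired"
    cr_present: bool = False
    cr_onset: Optional[float] = None
    cr_offset: Optional[float] = None
    ur_present: bool = False
    ur_onset: Optional[float] = None
    spontaneous_episodes: int = 0
    cr_metrics: Optional[Tuple[float, int, Optional[float]]] = None
    # (latency_s, n_bursts, burst_freq_hz)

    @property
    def cs_bearing(self) -> bool:
        return self.kind in ("paired", "cs_alone", "pseudo_cs")


@dataclass
class SessionSummary:
    n_trials: int
    cr_percent: float
    learner: bool
    acquisition_trial: Optional[int]
    block_cr_percent: List[float]
    extinction_trials: Optional[int]
    cr_trajectory: List[Tuple[float, int, Optional[float]]]
    block_size: int = 10
    criterion_percent: float = 20.0
    run_length: int = 2
    extinction_criterion: int = 3

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "cr_percent": self.cr_percent,
            "learner": self.learner,
            "acquisition_trial": self.acquisition_trial,
            "block_cr_percent": self.block_cr_percent,
            "extinction_trials": self.extinction_trials,
            "cr_trajectory": [list(m) for m in self.cr_trajectory],
            "block_size": self.block_size,
            "criterion_percent": self.criterion_percent,
            "run_length": self.run_length,
            "extinction_criterion": self.extinction_criterion,
        }


def classify_trial(
    episodes: Sequence[SwimEpisode],
    trial: TrialProtocol,
    ur_window_ms: float = 100.0,
    offset_response_window_s: float = 0.3,
) -> TrialOutcome:
    """Score one trial's episodes as CR / UR / spontaneous.

    CR window: [cs_onset, us_time) on US-bearing trials; on CS-alone trials
    the window extends past the CS offset by ``offset_response_window_s``
    (offset swimming counts, since no US truncates the trial).  The first
    qualifying episode supplies the CR metrics.
    """
    out = TrialOutcome(trial_index=trial.trial_index, kind=trial.kind)
    cr_window = None
    if trial.has_cs:
        if trial.has_us:
            cr_window = (trial.cs_onset, trial.us_time)
        else:
            cr_window = (trial.cs_onset, trial.cs_offset + offset_response_window_s)
    ur_window = None
    if trial.has_us:
        ur_window = (trial.us_time, trial.us_time + ur_window_ms / 1000.0)
        if cr_window is not None and cr_window[1] > ur_window[0]:
            raise ValueError("overlapping CR and UR windows")

    for ep in sorted(episodes, key=lambda e: e.onset):
        if cr_window and cr_window[0] <= ep.onset < cr_window[1]:
            ep.kind = "CR"
            if not out.cr_present:
                out.cr_present = True
                out.cr_onset = ep.onset
                out.cr_offset = ep.offset
                out.cr_metrics = (ep.onset - trial.cs_onset, ep.n_bursts,
                                  ep.burst_frequency)
            continue
        if ur_window and ur_window[0] <= ep.onset < ur_window[1]:
            ep.kind = "UR"
            if not out.ur_present:
                out.ur_present = True
                out.ur_onset = ep.onset
            continue
        ep.kind = "spontaneous"
        out.spontaneous_episodes += 1
    return out


def _cr_flags(outcomes: Sequence[TrialOutcome]) -> List[bool]:
    return [o.cr_present for o in outcomes if o.cs_bearing]


def learner_flag(outcomes: Sequence[TrialOutcome],
                 criterion_percent: float = 20.0,
                 reference_trials: int = 70) -> bool:
    """True when the CR percentage strictly exceeds the criterion.

    The percentage is taken over CS-bearing trials; shorter sessions than
    the 70-trial reference use the same percentage criterion.
    """
    flags = _cr_flags(outcomes)
    if not flags:
        raise ValueError("learner criterion requires at least one CS-bearing trial")
    return 100.0 * sum(flags) / len(flags) > criterion_percent


def acquisition_trial(outcomes: Sequence[TrialOutcome],
                      run_length: int = 2) -> Optional[int]:
    """1-based index of the first trial of the earliest consecutive-CR run."""
    flags = _cr_flags(outcomes)
    run = 0
    for i, f in enumerate(flags):
        run = run + 1 if f else 0
        if run >= run_length:
            return i - run_length + 2  # 1-based start of the run
    return None


def extinction_trials(outcomes: Sequence[TrialOutcome],
                      criterion: int = 3) -> Optional[int]:
    """CS-alone trials elapsed before the first run of ``criterion``
    consecutive non-CR trials begins; None if never reached."""
    flags = [o.cr_present for o in outcomes if o.kind == "cs_alone"]
    if not flags:
        raise ValueError("no CS-alone phase in these outcomes")
    run = 0
    for i, f in enumerate(flags):
        run = 0 if f else run + 1
        if run >= criterion:
            return i - criterion + 1
    return None


def cr_trajectory(outcomes: Sequence[TrialOutcome],
                  max_ordinal: int = 10) -> List[Tuple[float, int, Optional[float]]]:
    """CR metrics (latency, bursts, frequency) by CR ordinal, k = 1..10."""
    traj = [o.cr_metrics for o in outcomes
            if o.cr_present and o.cr_metrics is not None]
    return traj[:max_ordinal]


def summarize_session(
    outcomes: Sequence[TrialOutcome],
    block_size: int = 10,
    criterion_percent: float = 20.0,
    run_length: int = 2,
    extinction_criterion: int = 3,
) -> SessionSummary:
    """Session-level statistics from per-trial outcomes."""
    flags = _cr_flags(outcomes)
    if not flags:
        raise ValueError("session summary requires CS-bearing trials")
    cr_percent = 100.0 * sum(flags) / len(flags)
    blocks = [
        100.0 * float(np.mean(flags[i:i + block_size]))
        for i in range(0, len(flags), block_size)
    ]
    has_extinction = any(o.kind == "cs_alone" for o in outcomes)
    return SessionSummary(
        n_trials=len(outcomes),
        cr_percent=cr_percent,
        learner=learner_flag(outcomes, criterion_percent),
        acquisition_trial=acquisition_trial(outcomes, run_length),
        block_cr_percent=blocks,
        extinction_trials=(extinction_trials(outcomes, extinction_criterion)
                           if has_extinction else None),
        cr_trajectory=cr_trajectory(outcomes),
        block_size=block_size,
        criterion_percent=criterion_percent,
        run_length=run_length,
        extinction_criterion=extinction_criterion,
    )
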