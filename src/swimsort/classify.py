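"""Purkinje-cell classification from CR-associated complex spikes.

After learning, cells fall into three classes by how many complex spikes
accompany each conditional response: MCS (two or more on at least half of
CR trials), SCS (one on most trials), and ZCS (none, on every CR trial).
"During the CR" is operationalized as a padded window around the swim
episode (150 ms before onset to 300 ms after offset) because CR-associated
climbing-fiber events lead the onset or trail the offset by tens to a few
hundred ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .behavior import TrialOutcome
from .synthetic import TrialProtocol

CR_PAD_BEFORE_S = 0.150
CR_PAD_AFTER_S = 0.300
US_WINDOW_S = 0.100


@dataclass
class CellClassResult:
    cell_id: str
    label: str  # MCS | SCS | ZCS
    per_cr_trial_cxs_counts: List[int]
    fraction_us_trials_with_cxs: float
    mediolateral_position: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "label": self.label,
            "per_cr_trial_cxs_counts": list(self.per_cr_trial_cxs_counts),
            "fraction_us_trials_with_cxs": self.fraction_us_trials_with_cxs,
            "mediolateral_position": self.mediolateral_position,
        }


@dataclass
class LatencyStats:
    reference: str  # cs_onset | cr_onset | cr_offset | swim_onset
    per_trial_latencies: List[float]
    mean: float
    cv: Optional[float]  # SD/|mean|; None (flagged) when |mean| < 10 ms

    @property
    def defined(self) -> bool:
        return self.cv is not None


def _events_in(df: pd.DataFrame, trial: int, label: str,
               lo: float, hi: float, closed_right: bool = True) -> int:
    sel = (df["trial_index"] == trial) & (df["label"] == label)
    t = df.loc[sel, "time_s"]
    if closed_right:
        return int(((t >= lo) & (t <= hi)).sum())
    return int(((t >= lo) & (t < hi)).sum())


def classify_cell(
    event_table: pd.DataFrame,
    outcomes: Sequence[TrialOutcome],
    protocol: Sequence[TrialProtocol] = (),
    cr_pad: Tuple[float, float] = (CR_PAD_BEFORE_S, CR_PAD_AFTER_S),
    mediolateral_position: Optional[float] = None,
    cell_id: Optional[str] = None,
) -> CellClassResult:
    """Assign the MCS/SCS/ZCS label from per-CR-trial complex-spike counts.

    ZCS iff every CR-trial count is zero; otherwise MCS iff a strict
    majority of CR trials carry two or more complex spikes (ties resolve to
    SCS); otherwise SCS.  Also reports the fraction of US presentations
    followed within 100 ms by a complex spike.
    """
    cr_outcomes = [o for o in outcomes if o.cr_present and o.cr_onset is not None]
    if not cr_outcomes:
        raise ValueError("cell classification requires at least one CR trial")
    if cell_id is None:
        ids = event_table["cell_id"].unique() if len(event_table) else ["cell"]
        cell_id = str(ids[0])

    counts = [
        _events_in(event_table, o.trial_index, "complex",
                   o.cr_onset - cr_pad[0], o.cr_offset + cr_pad[1])
        for o in cr_outcomes
    ]
    if all(c == 0 for c in counts):
        label = "ZCS"
    elif np.mean([c >= 2 for c in counts]) > 0.5:
        label = "MCS"
    else:
        label = "SCS"

    us_trials = [p for p in protocol if p.has_us]
    frac_us = float("nan")
    if us_trials:
        hits = sum(
            _events_in(event_table, p.trial_index, "complex",
                       p.us_time, p.us_time + US_WINDOW_S) > 0
            for p in us_trials
        )
        frac_us = hits / len(us_trials)

    return CellClassResult(
        cell_id=cell_id, label=label, per_cr_trial_cxs_counts=counts,
        fraction_us_trials_with_cxs=frac_us,
        mediolateral_position=mediolateral_position,
    )


def latency_stats(
    event_times_by_trial: Dict[int, Sequence[float]],
    references_by_trial: Dict[int, float],
    reference: str = "cs_onset",
    nearest: bool = False,
) -> LatencyStats:
    """Per-trial latency of the first event after (or nearest to) a reference.

    ``nearest=True`` is the CR-onset convention, where events may lead the
    reference.  CV = SD/|mean| over trials, flagged undefined when the mean
    latency is within 10 ms of zero (the ratio diverges).
    """
    lats: List[float] = []
    for trial, ref in references_by_trial.items():
        times = np.sort(np.asarray(event_times_by_trial.get(trial, ()), float))
        if times.size == 0:
            continue
        if nearest:
            lats.append(float(times[np.argmin(np.abs(times - ref))] - ref))
        else:
            after = times[times >= ref]
            if after.size == 0:
                continue
            lats.append(float(after[0] - ref))
    if len(lats) < 2:
        raise ValueError("latency statistics require >= 2 trials with an event")
    mean = float(np.mean(lats))
    sd = float(np.std(lats, ddof=1))
    cv = None if abs(mean) < 0.010 else sd / abs(mean)
    return LatencyStats(reference=reference, per_trial_latencies=lats,
                        mean=mean, cv=cv)


def cs_window_counts(
    event_table: pd.DataFrame,
    protocol: Sequence[TrialProtocol],
    window_s: float = 0.5,
    align_trial: Optional[int] = None,
    label: str = "complex",
) -> pd.DataFrame:
    """Per-trial event counts in the first ``window_s`` of the CS.

    Counts are re-indexed relative to ``align_trial`` (trial 0 = the
    acquisition trial; the conventional fallback for pseudoconditioned fish
    is the cohort's median acquisition trial).
    """
    rows = []
    for p in protocol:
        if not p.has_cs:
            continue
        n = _events_in(event_table, p.trial_index, label,
                       p.cs_onset, p.cs_onset + window_s, closed_right=False)
        rel = p.trial_index - align_trial if align_trial is not None else None
        rows.append({"trial_index": p.trial_index, "relative_trial": rel,
                     "count": n})
    return pd.DataFrame(rows, columns=["trial_index", "relative_trial", "count"])


def stratify_counts(
    counts: pd.DataFrame,
    outcomes: Sequence[TrialOutcome],
    n_per_stratum: int = 3,
    require_no_cr: bool = True,
) -> Dict[str, float]:
    """Mean count over early / middle / late trial triplets.

    With ``require_no_cr`` only trials without a CR enter the strata, the
    convention for isolating stimulus-locked (rather than movement-locked)
    changes.
    """
    cr_by_trial = {o.trial_index: o.cr_present for o in outcomes}
    df = counts.copy()
    if require_no_cr:
        df = df[~df["trial_index"].map(cr_by_trial).fillna(False)]
    df = df.sort_values("trial_index")
    if len(df) < n_per_stratum:
        raise ValueError("not enough qualifying trials to stratify")
    mid0 = max((len(df) - n_per_stratum) // 2, 0)
    return {
        "early": float(df["count"].iloc[:n_per_stratum].mean()),
        "middle": float(df["count"].iloc[mid0:mid0 + n_per_stratum].mean()),
        "late": float(df["count"].iloc[-n_per_stratum:].mean()),
    }


def cxs_probability_near_cr(
    event_table: pd.DataFrame,
    cr_episodes: pd.DataFrame,
    window_s: float = 0.3,
) -> pd.DataFrame:
    """P(complex spike near CR onset / after CR offset) by CR ordinal.

    ``cr_episodes`` columns: cell_id, trial_index, ordinal, onset, offset.
    Onset window [onset - w, onset + w] (closed); offset window
    (offset, offset + w].  The onset window takes precedence: an event
    counted there cannot also satisfy the offset window.
    """
    rows = []
    for ordinal, grp in cr_episodes.groupby("ordinal"):
        on_hits = 0
        off_hits = 0
        for r in grp.itertuples(index=False):
            sel = ((event_table["cell_id"] == r.cell_id)
                   & (event_table["trial_index"] == r.trial_index)
                   & (event_table["label"] == "complex"))
            t = event_table.loc[sel, "time_s"].to_numpy()
            in_on = (t >= r.onset - window_s) & (t <= r.onset + window_s)
            in_off = (t > r.offset) & (t <= r.offset + window_s) & ~in_on
            on_hits += int(in_on.any())
            off_hits += int(in_off.any())
        n = len(grp)
        rows.append({"ordinal": int(ordinal), "n_crs": n,
                     "p_onset": on_hits / n, "p_offset": off_hits / n})
    return pd.DataFrame(rows, columns=["ordinal", "n_crs", "p_onset", "p_offset"])


def pf_count_during_cs(
    event_table: pd.DataFrame,
    protocol: Sequence[TrialProtocol],
    align_trial: Optional[int] = None,
) -> pd.DataFrame:
    """Per-trial pfEPSP counts over the whole CS window, acquisition-aligned."""
    rows = []
    for p in protocol:
        if not p.has_cs:
            continue
        n = _events_in(event_table, p.trial_index, "pfEPSP",
                       p.cs_onset, p.cs_offset, closed_right=False)
        rel = p.trial_index - align_trial if align_trial is not None else None
        rows.append({"trial_index": p.trial_index, "relative_trial": rel,
                     "count": n})
    return pd.DataFrame(rows, columns=["trial_index", "relative_trial", "count"])


def depolarization_latency(
    depol_intervals: Sequence,
    episodes: Sequence,
    max_lag_s: float = 1.0,
) -> List[float]:
    """Onset lag of each long depolarization to its nearest swim episode.

    Negative lags mean the depolarization led the movement.  Intervals with
    no episode onset within ``max_lag_s`` are skipped.
    """
    onsets = np.array([ep.onset for ep in episodes], float)
    lags: List[float] = []
    for interval in depol_intervals:
        if onsets.size == 0:
            break
        diffs = interval.onset - onsets
        k = int(np.argmin(np.abs(diffs)))
        if abs(diffs[k]) <= max_lag_s:
            lags.append(float(diffs[k]))
    return lags
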