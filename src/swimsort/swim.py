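"""Ventral-root analysis: rectified envelope, burst detection, episodes.

A fictive-swim episode is a group of motor bursts; bursts are detected as
supra-threshold runs of the rectified, 2 ms-smoothed signal, with the
threshold set relative to a quiet baseline window so the analysis is
invariant to recording gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import TraceRecording


@dataclass
class SwimEpisode:
    """One swim bout; onset/offset are the first and last burst times (s)."""

    onset: float
    offset: float
    burst_times: List[float]
    kind: str = "unassigned"  # spontaneous | CR | UR | unassigned

    def __post_init__(self) -> None:
        if len(self.burst_times) < 1:
            raise ValueError("an episode requires at least one burst")

    @property
    def n_bursts(self) -> int:
        return len(self.burst_times)

    @property
    def burst_frequency(self) -> Optional[float]:
        """(n - 1) / duration, Hz; undefined for single-burst episodes."""
        if self.n_bursts < 2:
            return None
        return (self.n_bursts - 1) / (self.offset - self.onset)


def envelope(vr: TraceRecording, window_ms: float = 2.0) -> np.ndarray:
    """Rectify and smooth with a centered moving average; length preserved."""
    if vr.modality != "ventral_root":
        raise ValueError("envelope is defined for ventral-root recordings")
    w = int(round(window_ms * vr.sampling_rate / 1000.0))
    if w < 3:
        raise ValueError(
            f"envelope window of {window_ms} ms spans fewer than 3 samples")
    return uniform_filter1d(np.abs(vr.values), size=w, mode="nearest")


def detect_bursts(
    env: np.ndarray,
    sampling_rate: float,
    baseline_window: Tuple[float, float],
    k_sd: float = 4.0,
    min_separation_ms: float = 5.0,
    us_time: Optional[float] = None,
    blank_ms: float = 2.0,
    min_duration_ms: float = 1.0,
) -> List[float]:
    """Burst onset times from an envelope.

    Threshold = baseline mean + ``k_sd`` x baseline SD; a burst is a maximal
    supra-threshold run at least ``min_duration_ms`` long (single-sample
    noise excursions are not bursts), with runs closer than
    ``min_separation_ms`` merged.  A blanking window around the US time
    excludes the shock artifact.
    """
    fs = sampling_rate
    i0 = max(int(round(baseline_window[0] * fs)), 0)
    i1 = min(int(round(baseline_window[1] * fs)), env.size)
    if i1 - i0 < 2:
        raise ValueError("empty baseline window for burst threshold")
    base = env[i0:i1]
    theta = float(np.mean(base) + k_sd * np.std(base))

    supra = env > theta
    if us_time is not None:
        b0 = int(round((us_time - blank_ms / 1000.0) * fs))
        b1 = int(round((us_time + blank_ms / 1000.0) * fs))
        supra[max(b0, 0): min(b1, env.size)] = False

    gap = min_separation_ms * fs / 1000.0
    min_run = max(int(round(min_duration_ms * fs / 1000.0)), 1)
    # onset refinement: the threshold crossing sits partway up the packet
    # ramp; walk back to where the envelope left the baseline band
    theta_low = float(np.mean(base) + 0.25 * k_sd * np.std(base))
    back_max = int(round(5e-3 * fs))
    onsets: List[float] = []
    last_end = -np.inf
    n = env.size
    i = 0
    while i < n:
        if supra[i]:
            j = i
            while j < n and supra[j]:
                j += 1
            if onsets and i - last_end < gap:
                last_end = j  # merge into the previous burst
            elif j - i >= min_run:
                k = i
                while k > max(i - back_max, 0) and env[k - 1] > theta_low:
                    k -= 1
                onsets.append(k / fs)
                last_end = j
            i = j
        else:
            i += 1
    return onsets


def segment_episodes(burst_times: Sequence[float],
                     max_gap_ms: float = 200.0) -> List[SwimEpisode]:
    """Group sorted bursts into episodes by inter-burst gap."""
    times = sorted(burst_times)
    episodes: List[SwimEpisode] = []
    if not times:
        return episodes
    group = [times[0]]
    for t in times[1:]:
        if (t - group[-1]) * 1000.0 <= max_gap_ms:
            group.append(t)
        else:
            episodes.append(SwimEpisode(group[0], group[-1], list(group)))
            group = [t]
    episodes.append(SwimEpisode(group[0], group[-1], list(group)))
    return episodes


def episode_latency(episode: SwimEpisode, reference_time: float) -> float:
    """Episode onset relative to a reference (s); may be negative."""
    return episode.onset - reference_time


def episodes_from_recording(
    vr: TraceRecording,
    baseline_window: Tuple[float, float],
    k_sd: float = 4.0,
    max_gap_ms: float = 200.0,
    min_separation_ms: float = 5.0,
    us_time: Optional[float] = None,
) -> List[SwimEpisode]:
    """envelope -> detect_bursts -> segment_episodes in one call."""
    env = envelope(vr)
    bursts = detect_bursts(env, vr.sampling_rate, baseline_window, k_sd,
                           min_separation_ms, us_time=us_time)
    return segment_episodes(bursts, max_gap_ms)
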