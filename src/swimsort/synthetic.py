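"""Conductance-based synthetic sessions with exact ground truth.

Simulates paired Purkinje-cell membrane-potential and ventral-root
recordings for a classical-conditioning experiment in larval zebrafish,
with every synaptic event, swim burst, and behavioral outcome known
exactly.  The membrane follows a single-compartment contract

    C dV/dt = -g_leak (V - E_leak) - sum_i g_i(t) (V - E_i) + I_applied

integrated with an exponential-Euler step (exact for conductances held
constant over a sample).  Climbing-fiber events inject large biexponential
excitatory conductances and appear as complex spikes rising directly from
baseline; simple spikes are stereotyped waveforms -- a small EPSP foot
followed by a fast regenerative conductance toward E_Na, then a
repolarizing conductance -- so their upstroke carries the programmed
inflection; parallel-fiber EPSPs are small excitatory conductances whose
summation produces long-lasting depolarizations.

Amplitude distributions are lognormal (positive, right-skewed) matched to
the configured mean/SD on the natural scale.  Simple-spike draws below a
regenerative floor are redrawn: a spike is all-or-none, and sub-floor
conductances correspond to failures that never become spikes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .io import TraceRecording

CELL_CLASSES = ("MCS", "SCS", "ZCS", "untrained")
TRIAL_KINDS = ("paired", "cs_alone", "us_alone", "pseudo_cs", "pseudo_us")

# Fixed reversal potentials (mV).  Not part of the fitted science; standard
# values for an excitatory synapse, Na spike, leak, and inhibition.
E_EXC = 0.0
E_NA = 55.0
E_LEAK = -60.0
E_INH = -75.0

# Biexponential kernel time constants, ms: (rise, decay)
CF_KERNEL = (0.3, 3.0)       # climbing-fiber conductance, rise <= 1 ms
PF_KERNEL = (0.8, 3.0)       # parallel-fiber EPSC-like conductance
SS_FOOT_KERNEL = (0.8, 2.0)  # EPSP foot preceding the regenerative rise
SS_REGEN_KERNEL = (0.25, 1.2)
SS_REPOL_KERNEL = (0.8, 4.0)
INH_KERNEL = (50.0, 250.0)   # slow inhibitory envelope (hyperpolarizations)

SS_FOOT_CONDUCTANCE = 0.3    # nS, fixed foot amplitude
SS_FOOT_LEAD_MS = 2.0        # foot onset precedes the regenerative onset
SS_REPOL_CONDUCTANCE = 2.5   # nS, K-like repolarization
SS_REPOL_DELAY_MS = 0.8
SS_REGEN_FLOOR = 0.9         # nS; smaller draws are spike failures, redrawn

# Minimum separations enforced by displacement (counts are preserved), ms
CF_DEADTIME_MS = 20.0
SS_DEADTIME_MS = 8.0
SS_AFTER_CF_MS = 15.0


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class CellSimConfig:
    """Biophysical parameters of one simulated Purkinje cell."""

    class_label: str = "untrained"
    capacitance: float = 10.7            # pF
    leak_conductance: float = 0.7        # nS (18.6 pA Arch current -> ~27 mV)
    leak_reversal: float = E_LEAK        # mV
    basal_complex_rate: float = 0.3      # events/s
    basal_simple_rate: float = 6.4
    basal_pf_rate: float = 8.0
    cf_conductance_mean: float = 4.86    # nS, natural-scale lognormal moments
    cf_conductance_sd: float = 0.25
    ss_upstroke_conductance_mean: float = 1.17
    ss_upstroke_conductance_sd: float = 0.5
    pf_conductance_mean: float = 0.17
    pf_conductance_sd: float = 0.08
    ss_conductance_floor: float = SS_REGEN_FLOOR  # nS; sub-floor draws redrawn
    noise_sd: float = 0.2                # mV
    offset_current: float = 0.0          # pA, amplifier artifact
    arch_current: float = 0.0            # pA outward during illumination
    arch_ss_suppression: float = 0.4 / 6.0  # simple-spike rate factor under light
    sampling_rate: float = 10_000.0      # Hz
    hyperpolarizing: bool = False        # inhibitory envelopes on episodes
    resting_potential: float = E_LEAK

    def __post_init__(self) -> None:
        if self.class_label not in CELL_CLASSES:
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")
        for r in (self.basal_complex_rate, self.basal_simple_rate, self.basal_pf_rate):
            if r < 0:
                raise ValueError("event rates must be >= 0")
        if not (self.cf_conductance_mean > self.ss_upstroke_conductance_mean
                > self.pf_conductance_mean > 0):
            raise ValueError("conductance means must satisfy cf > ss > pf > 0")


@dataclass
class TrialProtocol:
    """Stimulus timing for one trial (times in s from sweep start)."""

    trial_index: int
    kind: str = "paired"
    cs_onset: Optional[float] = None
    cs_offset: Optional[float] = None
    us_time: Optional[float] = None
    illumination_window: Optional[Tuple[float, float]] = None
    sweep_duration: float = 6.5

    def __post_init__(self) -> None:
        if self.kind not in TRIAL_KINDS:
            raise ValueError(f"unknown trial kind {self.kind!r}")
        if self.sweep_duration <= 0:
            raise ValueError("sweep_duration must be positive")
        if self.has_cs:
            if self.cs_onset is None or self.cs_offset is None:
                raise ValueError(f"{self.kind} trial requires a CS window")
            if not self.cs_onset < self.cs_offset:
                raise ValueError("cs_onset must precede cs_offset")
        if self.kind == "paired":
            if self.us_time is None:
                raise ValueError("paired trial requires us_time")
            if self.us_time < self.cs_offset:
                raise ValueError("paired trial requires us_time >= cs_offset")
        if self.illumination_window is not None and self.has_cs:
            lo, hi = self.illumination_window
            if lo > self.cs_onset or hi < self.cs_offset:
                raise ValueError("illumination window must contain the CS window")

    @property
    def has_cs(self) -> bool:
        return self.kind in ("paired", "cs_alone", "pseudo_cs")

    @property
    def has_us(self) -> bool:
        return self.kind in ("paired", "us_alone", "pseudo_us")

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["illumination_window"] is not None:
            d["illumination_window"] = list(d["illumination_window"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialProtocol":
        d = dict(d)
        if d.get("illumination_window") is not None:
            d["illumination_window"] = tuple(d["illumination_window"])
        return cls(**d)


@dataclass
class LearnerModel:
    """Per-fish behavioral trajectory for the conditioning task."""

    is_learner: bool = True
    acquisition_trial: int = 28
    plateau_cr_prob: float = 0.59
    pre_acquisition_cr_prob: float = 0.04
    cr_latency_initial: float = 1.1      # s after CS onset
    cr_latency_plateau: float = 0.85
    bursts_initial: float = 7.2
    bursts_plateau: float = 10.0
    burst_freq_initial: float = 23.0     # Hz
    burst_freq_plateau: float = 25.0
    ur_latency_mean: float = 0.0169      # s after the US
    ur_latency_sd: float = 0.003
    cr_latency_sd: float = 0.15
    bursts_sd: float = 1.6
    burst_freq_sd: float = 1.4
    extinction_decay: float = 0.5        # CR-probability multiplier per CS-alone trial
    spontaneous_episode_rate: float = 0.02  # episodes/s outside the trial window

    def __post_init__(self) -> None:
        for p in (self.plateau_cr_prob, self.pre_acquisition_cr_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.is_learner:
            if not self.plateau_cr_prob > self.pre_acquisition_cr_prob:
                raise ValueError("learners require plateau_cr_prob > pre_acquisition_cr_prob")
            if not self.cr_latency_plateau < self.cr_latency_initial:
                raise ValueError("learned CRs speed up: plateau latency must be shorter")


@dataclass
class EpisodePlan:
    """Ground-truth plan for one fictive-swim episode."""

    onset: float
    burst_times: List[float]
    kind: str = "spontaneous"  # spontaneous | CR | UR

    def __post_init__(self) -> None:
        self.burst_times = sorted(float(t) for t in self.burst_times)
        if self.burst_times and abs(self.burst_times[0] - self.onset) > 1e-9:
            self.onset = self.burst_times[0]

    @property
    def offset(self) -> float:
        return self.burst_times[-1] if self.burst_times else self.onset

    @property
    def n_bursts(self) -> int:
        return len(self.burst_times)


def make_episode(onset: float, n_bursts: int, burst_freq: float,
                 kind: str = "spontaneous") -> EpisodePlan:
    """Regularly spaced burst train: n bursts at burst_freq Hz from onset."""
    times = [onset + i / burst_freq for i in range(n_bursts)]
    return EpisodePlan(onset=onset, burst_times=times, kind=kind)


@dataclass
class GTEvent:
    time: float          # s; conductance onset (regenerative onset for spikes)
    label: str           # complex | simple | pfEPSP
    conductance: float   # nS injected


@dataclass
class GTTrial:
    trial_index: int
    cr: bool = False
    ur: bool = False
    events: List[GTEvent] = field(default_factory=list)
    episodes: List[EpisodePlan] = field(default_factory=list)


@dataclass
class GroundTruth:
    trials: List[GTTrial] = field(default_factory=list)

    def trial(self, index: int) -> GTTrial:
        for t in self.trials:
            if t.trial_index == index:
                return t
        raise KeyError(index)

    def to_dict(self) -> dict:
        return {
            "trials": [
                {
                    "trial_index": t.trial_index,
                    "cr": t.cr,
                    "ur": t.ur,
                    "events": [[e.time, e.label, e.conductance] for e in t.events],
                    "episodes": [
                        {"onset": ep.onset, "offset": ep.offset,
                         "burst_times": list(ep.burst_times), "kind": ep.kind}
                        for ep in t.episodes
                    ],
                }
                for t in self.trials
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        trials = []
        for t in d["trials"]:
            trials.append(GTTrial(
                trial_index=t["trial_index"], cr=t["cr"], ur=t["ur"],
                events=[GTEvent(e[0], e[1], e[2]) for e in t["events"]],
                episodes=[EpisodePlan(ep["onset"], ep["burst_times"], ep["kind"])
                          for ep in t["episodes"]],
            ))
        return cls(trials=trials)


@dataclass
class VentralRootConfig:
    sampling_rate: float = 10_000.0
    duration: float = 6.5               # s
    burst_duration_ms: float = 8.0
    burst_amplitude: float = 10.0       # in baseline-SD units when noise_sd = 1
    noise_sd: float = 1.0
    carrier_hz: float = 300.0


@dataclass
class SessionBundle:
    protocol: List[TrialProtocol]
    traces: List[TraceRecording]
    ventral_root: List[TraceRecording]
    ground_truth: Optional[GroundTruth] = None
    config: Optional[dict] = None
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# conductance kernels and membrane integration
# ---------------------------------------------------------------------------

def lognormal_params(mean: float, sd: float) -> Tuple[float, float]:
    """(mu, sigma) of a lognormal with the given natural-scale mean and SD."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def draw_lognormal(rng: np.random.Generator, mean: float, sd: float,
                   size: int, floor: float = 0.0) -> np.ndarray:
    mu, sigma = lognormal_params(mean, sd)
    out = rng.lognormal(mu, sigma, size)
    # Redraw sub-floor values (all-or-none regenerative events).
    for _ in range(100):
        bad = out < floor
        if not bad.any():
            break
        out[bad] = rng.lognormal(mu, sigma, int(bad.sum()))
    return out


def _unit_kernel(tau_r_ms: float, tau_d_ms: float, fs: float) -> np.ndarray:
    """Peak-normalized biexponential conductance kernel sampled at fs."""
    dt = 1000.0 / fs
    t_end = tau_d_ms * 8.0 + tau_r_ms * 4.0
    t = np.arange(0.0, t_end, dt)
    k = np.exp(-t / tau_d_ms) - np.exp(-t / tau_r_ms)
    peak = k.max()
    return k / peak if peak > 0 else k


def _add_kernel(arr: np.ndarray, onset_idx: int, kernel: np.ndarray,
                amplitude: float) -> None:
    if onset_idx >= arr.size:
        return
    start = max(onset_idx, 0)
    stop = min(onset_idx + kernel.size, arr.size)
    arr[start:stop] += amplitude * kernel[start - onset_idx: stop - onset_idx]


@njit(cache=True)
def _integrate_membrane(g_exc, g_na, g_inh, i_app, cap, g_leak, e_leak,
                        e_exc, e_na, e_inh, v0, dt_ms):  # pragma: no cover
    n = g_exc.size
    v = v0
    out = np.empty(n)
    for i in range(n):
        gt = g_leak + g_exc[i] + g_na[i] + g_inh[i]
        vinf = (g_leak * e_leak + g_exc[i] * e_exc + g_na[i] * e_na
                + g_inh[i] * e_inh + i_app[i]) / gt
        a = math.exp(-gt * dt_ms / cap)
        v = vinf + (v - vinf) * a
        out[i] = v
    return out


def _poisson_times(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    if rate <= 0 or duration <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))


def _thin(rng: np.random.Generator, times: np.ndarray,
          gates: Sequence[Tuple[float, float, float]]) -> np.ndarray:
    """Keep each event with the gate factor of the window it falls in."""
    keep = np.ones(times.size, dtype=np.bool_)
    for lo, hi, factor in gates:
        inside = (times >= lo) & (times < hi)
        if factor <= 0:
            keep &= ~inside
        elif factor < 1.0:
            keep &= ~inside | (rng.uniform(size=times.size) < factor)
    return times[keep]


def _enforce_spacing(times: np.ndarray, min_gap: float) -> np.ndarray:
    """Push later events forward so gaps are >= min_gap (counts preserved)."""
    out = np.sort(times).copy()
    for i in range(1, out.size):
        if out[i] - out[i - 1] < min_gap:
            out[i] = out[i - 1] + min_gap
    return out


# ---------------------------------------------------------------------------
# simulate_trace
# ---------------------------------------------------------------------------

def simulate_trace(
    config: CellSimConfig,
    protocol: TrialProtocol,
    episode_plan: Optional[Sequence[EpisodePlan]] = None,
    seed: int | np.random.Generator = 0,
    extra_events: Sequence[GTEvent] = (),
    rate_gates: Optional[dict] = None,
    inh_envelopes: Sequence[Tuple[float, float]] = (),
) -> Tuple[TraceRecording, List[GTEvent]]:
    """Simulate one current-clamp sweep; returns the trace and exact ground truth.

    Basal events are homogeneous Poisson at the configured rates (optionally
    modulated by ``rate_gates``: label -> [(t0, t1, factor)]); episode-locked
    class-template events arrive through ``extra_events``.  ``inh_envelopes``
    is a list of (onset_s, conductance_nS) slow inhibitory envelopes; when
    ``config.hyperpolarizing`` and an episode plan is given, one envelope is
    added per episode.
    """
    fs = config.sampling_rate
    if fs < 10_000:
        raise ValueError(
            f"sampling_rate {fs:g} Hz cannot resolve a 1 ms conductance rise; "
            "use >= 10 kHz"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = protocol.sweep_duration
    n = int(round(duration * fs))
    dt = 1.0 / fs

    gates = dict(rate_gates or {})
    if protocol.illumination_window is not None and config.arch_ss_suppression < 1.0 \
            and config.arch_current > 0:
        lo, hi = protocol.illumination_window
        gates.setdefault("simple", [])
        gates["simple"] = list(gates["simple"]) + [(lo, hi, config.arch_ss_suppression)]

    cf_times = _thin(rng, _poisson_times(rng, config.basal_complex_rate, duration),
                     gates.get("complex", ()))
    cf_times = _enforce_spacing(cf_times, CF_DEADTIME_MS / 1000.0)
    ss_times = _thin(rng, _poisson_times(rng, config.basal_simple_rate, duration),
                     gates.get("simple", ()))
    pf_times = _thin(rng, _poisson_times(rng, config.basal_pf_rate, duration),
                     gates.get("pfEPSP", ()))

    events: List[GTEvent] = []
    events.extend(GTEvent(t, "complex", g) for t, g in zip(
        cf_times, draw_lognormal(rng, config.cf_conductance_mean,
                                 config.cf_conductance_sd, cf_times.size)))
    events.extend(GTEvent(t, "simple", g) for t, g in zip(
        ss_times, draw_lognormal(rng, config.ss_upstroke_conductance_mean,
                                 config.ss_upstroke_conductance_sd,
                                 ss_times.size,
                                 floor=config.ss_conductance_floor)))
    events.extend(GTEvent(t, "pfEPSP", g) for t, g in zip(
        pf_times, draw_lognormal(rng, config.pf_conductance_mean,
                                 config.pf_conductance_sd, pf_times.size)))

    for ev in extra_events:
        g = ev.conductance
        if g is None or g <= 0:
            if ev.label == "complex":
                g = draw_lognormal(rng, config.cf_conductance_mean,
                                   config.cf_conductance_sd, 1)[0]
            elif ev.label == "simple":
                g = draw_lognormal(rng, config.ss_upstroke_conductance_mean,
                                   config.ss_upstroke_conductance_sd, 1,
                                   floor=config.ss_conductance_floor)[0]
            else:
                g = draw_lognormal(rng, config.pf_conductance_mean,
                                   config.pf_conductance_sd, 1)[0]
        events.append(GTEvent(ev.time, ev.label, float(g)))

    # displace simple spikes out of the complex-spike pause (the climbing
    # fiber suppresses simple spiking around each complex spike) and away
    # from each other; counts are preserved
    cf_all = np.sort([e.time for e in events if e.label == "complex"])
    ss_list = _enforce_spacing(
        np.array([e.time for e in events if e.label == "simple"]),
        SS_DEADTIME_MS / 1000.0)
    if cf_all.size and ss_list.size:
        pause = SS_AFTER_CF_MS / 1000.0
        for _ in range(4):
            moved = False
            for i, t in enumerate(ss_list):
                near = np.abs(cf_all - t) < pause
                if near.any():
                    j = int(np.argmax(near))
                    ss_list[i] = cf_all[j] + pause
                    moved = True
            ss_list = _enforce_spacing(ss_list, SS_DEADTIME_MS / 1000.0)
            if not moved:
                break
    ss_g = [e.conductance for e in events if e.label == "simple"]
    events = [e for e in events if e.label != "simple"]
    events.extend(GTEvent(t, "simple", g) for t, g in zip(ss_list, ss_g))

    # snap to the sample grid and keep events strictly inside the sweep
    margin = 0.05
    snapped: List[GTEvent] = []
    for e in events:
        t = round(e.time / dt) * dt
        if margin <= t <= duration - margin:
            snapped.append(GTEvent(t, e.label, e.conductance))
    snapped.sort(key=lambda e: (e.time, e.label))

    g_exc = np.zeros(n)
    g_na = np.zeros(n)
    g_inh = np.zeros(n)
    k_cf = _unit_kernel(*CF_KERNEL, fs)
    k_pf = _unit_kernel(*PF_KERNEL, fs)
    k_foot = _unit_kernel(*SS_FOOT_KERNEL, fs)
    k_regen = _unit_kernel(*SS_REGEN_KERNEL, fs)
    k_repol = _unit_kernel(*SS_REPOL_KERNEL, fs)
    k_inh = _unit_kernel(*INH_KERNEL, fs)

    for e in snapped:
        idx = int(round(e.time * fs))
        if e.label == "complex":
            _add_kernel(g_exc, idx, k_cf, e.conductance)
        elif e.label == "pfEPSP":
            _add_kernel(g_exc, idx, k_pf, e.conductance)
        else:
            _add_kernel(g_exc, idx - int(round(SS_FOOT_LEAD_MS * fs / 1000.0)),
                        k_foot, SS_FOOT_CONDUCTANCE)
            _add_kernel(g_na, idx, k_regen, e.conductance)
            _add_kernel(g_inh, idx + int(round(SS_REPOL_DELAY_MS * fs / 1000.0)),
                        k_repol, SS_REPOL_CONDUCTANCE)

    envelopes = list(inh_envelopes)
    if config.hyperpolarizing and episode_plan:
        for ep in episode_plan:
            envelopes.append((ep.onset, float(rng.uniform(0.5, 0.9))))
    for onset, amp in envelopes:
        _add_kernel(g_inh, int(round(onset * fs)), k_inh, amp)

    i_app = np.full(n, config.offset_current)
    if protocol.illumination_window is not None and config.arch_current != 0.0:
        lo, hi = protocol.illumination_window
        i0, i1 = int(round(lo * fs)), int(round(hi * fs))
        i_app[max(i0, 0):min(i1, n)] -= config.arch_current

    v = _integrate_membrane(
        g_exc, g_na, g_inh, i_app,
        config.capacitance, config.leak_conductance, config.leak_reversal,
        E_EXC, E_NA, E_INH, config.resting_potential, 1000.0 / fs,
    )
    if config.noise_sd > 0:
        v = v + rng.normal(0.0, config.noise_sd, n)

    trace = TraceRecording(v, fs, modality="current_clamp",
                           capacitance=config.capacitance,
                           trial_index=protocol.trial_index)
    return trace, snapped


def simulate_voltage_clamp_trace(
    config: CellSimConfig,
    protocol: TrialProtocol,
    events: Sequence[GTEvent],
    seed: int | np.random.Generator = 0,
    holding_potential: float = -60.0,
    noise_sd_pa: float = 2.0,
) -> TraceRecording:
    """Synaptic current at a fixed holding potential (stored, only summarized)."""
    fs = config.sampling_rate
    n = int(round(protocol.sweep_duration * fs))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k_cf = _unit_kernel(*CF_KERNEL, fs)
    k_pf = _unit_kernel(*PF_KERNEL, fs)
    g = np.zeros(n)
    for e in events:
        if e.label == "complex":
            _add_kernel(g, int(round(e.time * fs)), k_cf, e.conductance)
        elif e.label == "pfEPSP":
            _add_kernel(g, int(round(e.time * fs)), k_pf, e.conductance)
    i = g * (holding_potential - E_EXC) + rng.normal(0.0, noise_sd_pa, n)
    return TraceRecording(i, fs, modality="voltage_clamp",
                          holding_potential=holding_potential,
                          trial_index=protocol.trial_index)


# ---------------------------------------------------------------------------
# ventral root
# ---------------------------------------------------------------------------

def simulate_ventral_root(
    episode_plan: Sequence[EpisodePlan],
    vr_config: Optional[VentralRootConfig] = None,
    seed: int | np.random.Generator = 0,
) -> Tuple[TraceRecording, List[EpisodePlan]]:
    """Render swim episodes as burst packets over zero-mean baseline noise."""
    cfg = vr_config or VentralRootConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    episodes = sorted(episode_plan, key=lambda e: e.onset)
    for a, b in zip(episodes, episodes[1:]):
        if b.onset <= a.offset:
            raise ValueError(
                f"overlapping episodes at {a.onset:.3f}-{a.offset:.3f} s "
                f"and {b.onset:.3f} s")
    fs = cfg.sampling_rate
    n = int(round(cfg.duration * fs))
    sig = rng.normal(0.0, cfg.noise_sd, n)
    m = max(int(round(cfg.burst_duration_ms * fs / 1000.0)), 4)
    t_pack = np.arange(m) / fs
    env = np.hanning(m)
    for ep in episodes:
        for bt in ep.burst_times:
            i0 = int(round(bt * fs))
            if i0 >= n:
                continue
            phase = rng.uniform(0.0, 2.0 * np.pi)
            packet = cfg.burst_amplitude * env * np.sin(
                2.0 * np.pi * cfg.carrier_hz * t_pack + phase)
            stop = min(i0 + m, n)
            sig[i0:stop] += packet[: stop - i0]
    trace = TraceRecording(sig, fs, modality="ventral_root")
    return trace, episodes


# ---------------------------------------------------------------------------
# behavior model
# ---------------------------------------------------------------------------

@dataclass
class TrialPlan:
    cr: bool = False
    cr_onset: Optional[float] = None
    cr_n_bursts: Optional[int] = None
    cr_burst_freq: Optional[float] = None
    ur: bool = False
    ur_onset: Optional[float] = None
    spontaneous: List[Tuple[float, int, float]] = field(default_factory=list)


def cr_probability(model: LearnerModel, trial: TrialProtocol,
                   cs_alone_streak: int = 0) -> float:
    """Programmed CR probability for one trial.

    Learners ramp linearly from the pre-acquisition probability to the
    plateau over the five trials leading up to the acquisition trial and
    stay at plateau from it on.  CS-alone trials multiply the probability by
    ``extinction_decay`` per consecutive presentation.
    """
    if not trial.has_cs:
        return 0.0
    if trial.kind == "pseudo_cs" or not model.is_learner:
        p = model.pre_acquisition_cr_prob
    else:
        idx = trial.trial_index
        acq = model.acquisition_trial
        if idx >= acq:
            p = model.plateau_cr_prob
        elif idx <= acq - 5:
            p = model.pre_acquisition_cr_prob
        else:
            frac = (idx - (acq - 5)) / 5.0
            p = model.pre_acquisition_cr_prob + frac * (
                model.plateau_cr_prob - model.pre_acquisition_cr_prob)
    if trial.kind == "cs_alone":
        p *= model.extinction_decay ** cs_alone_streak
    return float(min(max(p, 0.0), 1.0))


def behavior_model(
    model: LearnerModel,
    trial: TrialProtocol,
    seed: int | np.random.Generator = 0,
    cs_alone_streak: int = 0,
    n_prior_crs: int = 0,
) -> TrialPlan:
    """Draw the behavioral plan (CR/UR/spontaneous episodes) for one trial."""
    if trial.trial_index < 1:
        raise ValueError("trial_index must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    plan = TrialPlan()

    if trial.has_cs:
        p = cr_probability(model, trial, cs_alone_streak)
        if rng.uniform() < p:
            k = n_prior_crs + 1
            f = min(1.0, (k - 1) / 4.0)  # plateau by about the fifth CR

            def interp(a, b):
                return a + f * (b - a)

            latency = interp(model.cr_latency_initial, model.cr_latency_plateau)
            latency += rng.normal(0.0, model.cr_latency_sd)
            cs_len = trial.cs_offset - trial.cs_onset
            latency = float(np.clip(latency, 0.15, cs_len - 0.1))
            plan.cr = True
            plan.cr_onset = trial.cs_onset + latency
            plan.cr_n_bursts = int(max(2, round(
                interp(model.bursts_initial, model.bursts_plateau)
                + rng.normal(0.0, model.bursts_sd))))
            plan.cr_burst_freq = float(max(15.0, interp(
                model.burst_freq_initial, model.burst_freq_plateau)
                + rng.normal(0.0, model.burst_freq_sd)))

    if trial.has_us:
        plan.ur = True  # the US elicits a reflex response with full reliability
        plan.ur_onset = trial.us_time + max(
            0.004, rng.normal(model.ur_latency_mean, model.ur_latency_sd))

    n_spont = rng.poisson(model.spontaneous_episode_rate * trial.sweep_duration)
    lo = trial.cs_onset - 1.0 if trial.has_cs else (
        trial.us_time - 1.0 if trial.has_us else trial.sweep_duration)
    hi = (trial.us_time if trial.has_us else
          (trial.cs_offset if trial.has_cs else 0.0)) + 1.0
    for _ in range(n_spont):
        t = rng.uniform(0.3, trial.sweep_duration - 0.8)
        if lo <= t <= hi:
            continue
        nb = int(rng.integers(4, 9))
        plan.spontaneous.append((float(t), nb, float(rng.normal(22.0, 2.0))))
    plan.spontaneous.sort()
    return plan


def plan_to_episodes(plan: TrialPlan, trial: TrialProtocol) -> List[EpisodePlan]:
    """Turn a behavioral plan into non-overlapping ground-truth episodes."""
    eps: List[EpisodePlan] = []
    for t, nb, freq in plan.spontaneous:
        eps.append(make_episode(t, nb, freq, "spontaneous"))
    if plan.cr:
        eps.append(make_episode(plan.cr_onset, plan.cr_n_bursts,
                                plan.cr_burst_freq, "CR"))
    if plan.ur:
        eps.append(make_episode(plan.ur_onset, 8, 28.0, "UR"))
    eps.sort(key=lambda e: e.onset)
    kept: List[EpisodePlan] = []
    for ep in eps:
        if kept and ep.onset <= kept[-1].offset + 0.05:
            if ep.kind != "spontaneous" and kept[-1].kind == "spontaneous":
                kept[-1] = ep  # stimulus-locked episodes win collisions
            continue
        kept.append(ep)
    return kept


# ---------------------------------------------------------------------------
# session simulation with class templates
# ---------------------------------------------------------------------------

@dataclass
class ClassTemplate:
    """Episode-locked event statistics for one Purkinje-cell class."""

    cr_pad_before: float = 0.15
    cr_pad_after: float = 0.30
    # MCS: >= 2 complex spikes per CR, CS-locked complex spikes grow with training
    mcs_extra_cxs_prob: float = 0.4
    mcs_cs_count_initial: float = 0.3   # mean cxs in first 500 ms of CS, early
    mcs_cs_count_final: float = 1.5     # after acquisition
    # SCS: exactly one CR-associated complex spike
    scs_onset_prob: float = 40.0 / 53.0
    scs_onset_latency: float = -0.074   # s, relative to CR onset
    scs_onset_jitter: float = 0.030
    scs_offset_latency: float = 0.223   # s, after CR offset
    scs_offset_jitter: float = 0.028
    # ZCS: no CR complex spikes; parallel-fiber drive grows with training
    zcs_pf_rate_initial: float = 2.5    # events/s during the CS
    zcs_pf_rate_final: float = 20.0
    zcs_depol_lead: float = 0.171       # barrage starts this far before CR onset
    zcs_barrage_rate: float = 100.0     # Hz
    cr_pf_barrage_rate: float = 50.0    # MCS/SCS parallel-fiber drive during CR
    us_cxs_prob: dict = field(default_factory=lambda: {
        "MCS": 0.67, "SCS": 0.46, "ZCS": 0.35, "untrained": 0.4})
    us_cxs_latency: Tuple[float, float] = (0.02, 0.08)


@dataclass
class SessionConfig:
    cell: CellSimConfig = field(default_factory=CellSimConfig)
    learner: LearnerModel = field(default_factory=LearnerModel)
    template: ClassTemplate = field(default_factory=ClassTemplate)
    n_paired: int = 20
    n_extinction: int = 0
    pseudo: bool = False                # pseudoconditioning: unpaired CS / US
    cs_onset: float = 3.0
    cs_duration: float = 2.0
    post_us: float = 1.5
    arch: bool = False
    illumination_margin: float = 0.1
    vr: VentralRootConfig = field(default_factory=VentralRootConfig)
    cell_id: str = "cell00"

    @property
    def sweep_duration(self) -> float:
        return self.cs_onset + self.cs_duration + self.post_us

    def to_dict(self) -> dict:
        return asdict(self)


def build_protocol(config: SessionConfig) -> List[TrialProtocol]:
    trials: List[TrialProtocol] = []
    cs_off = config.cs_onset + config.cs_duration
    illum = None
    if config.arch:
        illum = (config.cs_onset - config.illumination_margin,
                 cs_off + config.illumination_margin)
    idx = 0
    for i in range(config.n_paired):
        idx += 1
        if config.pseudo:
            if i % 2 == 0:
                trials.append(TrialProtocol(idx, "pseudo_cs", config.cs_onset,
                                            cs_off, None, illum,
                                            config.sweep_duration))
            else:
                trials.append(TrialProtocol(idx, "pseudo_us", None, None,
                                            cs_off, None, config.sweep_duration))
        else:
            trials.append(TrialProtocol(idx, "paired", config.cs_onset, cs_off,
                                        cs_off, illum, config.sweep_duration))
    for _ in range(config.n_extinction):
        idx += 1
        trials.append(TrialProtocol(idx, "cs_alone", config.cs_onset, cs_off,
                                    None, illum, config.sweep_duration))
    return trials


def _template_events(
    label: str, tpl: ClassTemplate, trial: TrialProtocol, plan: TrialPlan,
    acq: int, rng: np.random.Generator, learning: bool = True,
) -> Tuple[List[GTEvent], dict]:
    """Episode-locked events and basal-rate gates for one trial."""
    events: List[GTEvent] = []
    gates: dict = {}
    cr_window = None
    if plan.cr:
        cr_off = plan.cr_onset + max(plan.cr_n_bursts - 1, 1) / plan.cr_burst_freq
        cr_window = (plan.cr_onset - tpl.cr_pad_before, cr_off + tpl.cr_pad_after)

    # training-related growth of CS-locked drive; flat for fish that do not learn
    ramp = float(np.clip((trial.trial_index - (acq - 5)) / 10.0, 0.0, 1.0)) \
        if learning else 0.0

    if label == "MCS":
        if cr_window is not None:
            k = 2 + int(rng.uniform() < tpl.mcs_extra_cxs_prob)
            lo = plan.cr_onset - 0.10
            hi = cr_window[1] - tpl.cr_pad_after + 0.20
            times = np.sort(rng.uniform(lo, hi, k))
            # climbing fibers fire well below ~15 Hz: spread CR-locked events
            times = _enforce_spacing(times, 0.060)
            events.extend(GTEvent(float(t), "complex", 0.0) for t in times)
        if trial.has_cs:
            mean = tpl.mcs_cs_count_initial + ramp * (
                tpl.mcs_cs_count_final - tpl.mcs_cs_count_initial)
            for _ in range(rng.poisson(mean)):
                events.append(GTEvent(
                    float(trial.cs_onset + rng.uniform(0.0, 0.5)), "complex", 0.0))
    elif label == "SCS":
        if cr_window is not None:
            if rng.uniform() < tpl.scs_onset_prob:
                t = plan.cr_onset + tpl.scs_onset_latency \
                    + rng.normal(0.0, tpl.scs_onset_jitter)
            else:
                t = (cr_window[1] - tpl.cr_pad_after) + tpl.scs_offset_latency \
                    + rng.normal(0.0, tpl.scs_offset_jitter)
            t = float(np.clip(t, cr_window[0] + 0.005, cr_window[1] - 0.005))
            events.append(GTEvent(t, "complex", 0.0))
            gates.setdefault("complex", []).append((cr_window[0] - 0.05,
                                                    cr_window[1] + 0.05, 0.0))
    elif label == "ZCS":
        if cr_window is not None:
            gates.setdefault("complex", []).append((cr_window[0] - 0.05,
                                                    cr_window[1] + 0.05, 0.0))
            # parallel-fiber barrage whose summated depolarization leads the CR
            start = plan.cr_onset - tpl.zcs_depol_lead
            stop = cr_window[1] - tpl.cr_pad_after
            tt = start
            while tt < stop:
                events.append(GTEvent(
                    float(tt + rng.normal(0.0, 0.002)), "pfEPSP", 0.0))
                tt += 1.0 / tpl.zcs_barrage_rate
        if trial.has_cs:
            rate = tpl.zcs_pf_rate_initial + ramp * (
                tpl.zcs_pf_rate_final - tpl.zcs_pf_rate_initial)
            for t in _poisson_times(rng, rate, trial.cs_offset - trial.cs_onset):
                events.append(GTEvent(float(trial.cs_onset + t), "pfEPSP", 0.0))

    if label in ("MCS", "SCS") and cr_window is not None:
        start, stop = plan.cr_onset, cr_window[1] - tpl.cr_pad_after
        for t in _poisson_times(rng, tpl.cr_pf_barrage_rate, stop - start):
            events.append(GTEvent(float(start + t), "pfEPSP", 0.0))

    if trial.has_us and rng.uniform() < tpl.us_cxs_prob.get(label, 0.0):
        lo, hi = tpl.us_cxs_latency
        events.append(GTEvent(float(trial.us_time + rng.uniform(lo, hi)),
                              "complex", 0.0))
    return events, gates


def simulate_session(session_config: SessionConfig,
                     seed: int = 0) -> SessionBundle:
    """Simulate a full conditioning session for one cell.

    Emits per-trial intracellular and ventral-root recordings plus complete
    ground truth; Purkinje event timing follows the configured class
    template and the behavior follows :func:`behavior_model`.
    """
    cfg = session_config
    if cfg.n_paired < 1:
        raise ValueError("session requires at least one trial")
    protocol = build_protocol(cfg)
    root = np.random.SeedSequence(seed)
    children = root.spawn(2 * len(protocol) + 1)
    behav_rng = np.random.default_rng(children[0])

    traces: List[TraceRecording] = []
    ventral: List[TraceRecording] = []
    gt_trials: List[GTTrial] = []

    streak = 0
    n_crs = 0
    acq = cfg.learner.acquisition_trial
    for i, trial in enumerate(protocol):
        plan = behavior_model(cfg.learner, trial, behav_rng,
                              cs_alone_streak=streak, n_prior_crs=n_crs)
        if trial.kind == "cs_alone":
            streak += 1
        if plan.cr:
            n_crs += 1
        episodes = plan_to_episodes(plan, trial)

        trial_rng = np.random.default_rng(children[1 + 2 * i])
        learning = cfg.learner.is_learner and not cfg.pseudo
        extra, gates = _template_events(cfg.cell.class_label, cfg.template,
                                        trial, plan, acq, trial_rng,
                                        learning=learning)
        cell = cfg.cell
        if cfg.arch and cell.arch_current == 0.0:
            cell = CellSimConfig(**{**asdict(cell), "arch_current": 18.6})
        trace, events = simulate_trace(
            cell, trial, episode_plan=episodes, seed=trial_rng,
            extra_events=extra, rate_gates=gates)
        trace.cell_id = cfg.cell_id
        vr_cfg = VentralRootConfig(**{**asdict(cfg.vr),
                                      "duration": trial.sweep_duration})
        vr, episodes = simulate_ventral_root(
            episodes, vr_cfg, np.random.default_rng(children[2 + 2 * i]))
        if trial.has_us:  # stimulation artifact on the ventral-root channel
            fs_vr = vr.sampling_rate
            a0 = int(round(trial.us_time * fs_vr))
            a1 = min(a0 + int(round(0.001 * fs_vr)), vr.values.size)
            vr.values[a0:a1] += 3.0 * cfg.vr.burst_amplitude
        vr.cell_id = cfg.cell_id
        vr.trial_index = trial.trial_index
        traces.append(trace)
        ventral.append(vr)
        gt_trials.append(GTTrial(trial.trial_index, cr=plan.cr, ur=plan.ur,
                                 events=events, episodes=episodes))

    return SessionBundle(
        protocol=protocol, traces=traces, ventral_root=ventral,
        ground_truth=GroundTruth(gt_trials), config=cfg.to_dict(), seed=seed,
    )
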