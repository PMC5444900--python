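"""Cohort-scale validation studies on simulated ground truth.

Each study regenerates its own synthetic data from a seed, runs the
corresponding analysis stage, and measures recovery of the programmed
ground truth: unit-conversion arithmetic, spike-sorting F1, conductance
normalization and histogram overlap, behavioral scoring, cell-class
recovery, and optogenetic simple-spike suppression.  These functions back
both the acceptance machinery and the test suite.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import classify as cls
from . import events as evt
from .pipeline import detect_session_events, match_event_times, score_session_swim
from .swim import SwimEpisode
from .synthetic import (
    E_EXC,
    E_NA,
    CellSimConfig,
    LearnerModel,
    SessionConfig,
    TrialProtocol,
    behavior_model,
    plan_to_episodes,
    simulate_session,
    simulate_trace,
)

MATCH_TOL = {"complex": 0.003, "simple": 0.003, "pfEPSP": 0.010}


# ---------------------------------------------------------------------------
# unit-conversion chain
# ---------------------------------------------------------------------------

def synaptic_current(conductance_ns: float, voltage_mv: float,
                     reversal_mv: float) -> float:
    """Instantaneous synaptic current in pA (negative = inward)."""
    return conductance_ns * (voltage_mv - reversal_mv)


def unit_conversions(capacitance_pf: float = 10.7) -> Dict[str, float]:
    """The worked unit-conversion chain of the event-sorting procedure.

    * current step -> dV/dt on a passive cell, measured from an actual
      simulated sweep (10 pF, -250 pA, zero leak);
    * climbing-fiber and parallel-fiber conductances -> EPSC amplitude at
      -60 mV;
    * simple-spike upstroke dV/dt -> underlying Na conductance and current
      near -30 mV.
    """
    # measured, not computed by formula: slope of a simulated passive sweep
    cfg = CellSimConfig(
        basal_complex_rate=0.0, basal_simple_rate=0.0, basal_pf_rate=0.0,
        noise_sd=0.0, capacitance=10.0, leak_conductance=1e-9,
        offset_current=-250.0)
    proto = TrialProtocol(1, "us_alone", us_time=0.05, sweep_duration=0.1)
    trace, _ = simulate_trace(cfg, proto, seed=0)
    d = evt.derivative(trace, 0.2)
    step_dvdt = float(np.median(d[5:-5]))

    cf_current = synaptic_current(4.86, -60.0, E_EXC)
    pf_current = synaptic_current(0.17, -60.0, E_EXC)
    ss_g, _ = evt.estimate_conductance(10.5, -30.0, capacitance_pf, E_NA)
    ss_current = synaptic_current(ss_g, -30.0, E_NA)
    return {
        "current_step_dvdt_mv_per_ms": step_dvdt,        # -25 mV/ms
        "cf_epsc_pa_at_minus60": cf_current,             # about -292 pA
        "pf_epsc_pa_at_minus60": pf_current,             # about -10 pA
        "ss_upstroke_conductance_ns": float(ss_g),       # about 1.32 nS
        "ss_upstroke_current_pa": ss_current,            # about -112 pA
    }


# ---------------------------------------------------------------------------
# detection recovery and conductance distributions
# ---------------------------------------------------------------------------

def cohort_configs(n: int, seed: int, base: Optional[CellSimConfig] = None,
                   cell_scale_sd: float = 0.3) -> List[CellSimConfig]:
    """Cells with per-cell synaptic-conductance scales.

    Event amplitudes vary from cell to cell in real recordings.  Each cell
    carries a shared synaptic scale factor (clipped to [1.0, 1.6] so every
    cell's events stay resolvable at the fixed cascade thresholds — quieter
    cells are what the adaptive mode is for) plus a small climbing-fiber /
    simple-spike ratio spread.  Normalizing to the cell's own mean
    complex-spike conductance cancels the shared factor exactly, which is
    what the normalization step is for: the pooled absolute distributions
    spread with the cohort while the normalized ones do not.
    """
    rng = np.random.default_rng(seed)
    base = base or CellSimConfig()
    out = []
    for _ in range(n):
        # a shared synaptic scale (cancelled exactly by per-cell
        # normalization) plus a small climbing-fiber/simple-spike ratio
        # spread that survives it
        s_shared = float(np.clip(rng.lognormal(0.1, cell_scale_sd), 1.0, 1.6))
        s_rel = float(np.clip(rng.lognormal(0.0, 0.15), 0.85, 1.15))
        s_cf = s_shared
        s_ss = float(np.clip(s_shared * s_rel, 0.9, 1.5))
        out.append(replace(
            base,
            cf_conductance_mean=base.cf_conductance_mean * s_cf,
            cf_conductance_sd=base.cf_conductance_sd * s_cf,
            ss_upstroke_conductance_mean=(
                base.ss_upstroke_conductance_mean * s_ss),
            ss_upstroke_conductance_sd=(
                base.ss_upstroke_conductance_sd * s_ss),
            ss_conductance_floor=base.ss_conductance_floor * s_ss,
        ))
    return out


def detection_study(n_sweeps: int = 50, sweep_duration: float = 10.0,
                    seed: int = 0, cell_scale_sd: float = 0.3) -> dict:
    """Sorter recovery on basal-activity sweeps, one simulated cell each.

    Returns per-label precision/recall/F1 pooled over sweeps plus the
    per-cell detected event table (for the normalization study).
    """
    configs = cohort_configs(n_sweeps, seed, cell_scale_sd=cell_scale_sd)
    ss_root = np.random.SeedSequence(seed + 1).spawn(n_sweeps)
    proto = TrialProtocol(1, "us_alone", us_time=sweep_duration - 0.2,
                          sweep_duration=sweep_duration)
    counts = {lab: {"hits": 0, "true": 0, "det": 0}
              for lab in ("complex", "simple", "pfEPSP")}
    tables = []
    for i, cfg in enumerate(configs):
        rng = np.random.default_rng(ss_root[i])
        trace, truth = simulate_trace(cfg, proto, seed=rng)
        trace.cell_id = f"cell{i:02d}"
        det = evt.detect_events(trace)
        for lab in counts:
            t = [e.time for e in truth if e.label == lab]
            d = [e.time for e in det[lab]]
            counts[lab]["hits"] += match_event_times(t, d, MATCH_TOL[lab])
            counts[lab]["true"] += len(t)
            counts[lab]["det"] += len(d)
        tables.append(evt.events_to_table(det, cell_id=trace.cell_id,
                                          trial_index=1))
    metrics = {}
    for lab, c in counts.items():
        p = c["hits"] / c["det"] if c["det"] else float("nan")
        r = c["hits"] / c["true"] if c["true"] else float("nan")
        f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        metrics[lab] = {"precision": p, "recall": r, "f1": f1,
                        "n_true": c["true"], "n_detected": c["det"]}
    return {"metrics": metrics,
            "event_table": pd.concat(tables, ignore_index=True)}


def normalization_study(event_table: pd.DataFrame,
                        bin_width_abs: float = 0.02,
                        bin_width_norm: float = 0.005) -> dict:
    """Per-cell conductance normalization and complex/simple overlap.

    Mirrors the three-level comparison: pooled absolute overlap, pooled
    normalized overlap, and the mean within-cell normalized overlap.
    """
    df, skipped = evt.normalize_conductances(event_table)
    cxs = df[df["label"] == "complex"]
    ss = df[df["label"] == "simple"]
    per_cell_means = cxs.groupby("cell_id")["normalized_conductance"].mean()

    within = []
    for cell, sub in df.groupby("cell_id"):
        a = sub.loc[sub["label"] == "complex", "normalized_conductance"].dropna()
        b = sub.loc[sub["label"] == "simple", "normalized_conductance"].dropna()
        if len(a) and len(b):
            within.append(evt.distribution_overlap(a, b, bin_width_norm))
    return {
        "mean_normalized_cxs_per_cell": per_cell_means.to_dict(),
        "max_norm_mean_error": float(np.max(np.abs(per_cell_means - 1.0)))
        if len(per_cell_means) else float("nan"),
        "pooled_absolute_overlap_percent": evt.distribution_overlap(
            cxs["conductance_ns"], ss["conductance_ns"], bin_width_abs),
        "pooled_normalized_overlap_percent": evt.distribution_overlap(
            cxs["normalized_conductance"].dropna(),
            ss["normalized_conductance"].dropna(), bin_width_norm),
        "within_cell_normalized_overlap_percent": float(np.mean(within))
        if within else float("nan"),
        "cells_skipped": skipped,
    }


def overlap_bruteforce(sample_a, sample_b, bin_width: float) -> float:
    """Independent shared-bin min-sum oracle (dict-of-bins enumeration)."""
    a = [float(x) for x in sample_a]
    b = [float(x) for x in sample_b]
    pa: Dict[int, float] = {}
    pb: Dict[int, float] = {}
    for x in a:
        k = int(np.floor(x / bin_width))
        pa[k] = pa.get(k, 0.0) + 1.0 / len(a)
    for x in b:
        k = int(np.floor(x / bin_width))
        pb[k] = pb.get(k, 0.0) + 1.0 / len(b)
    return 100.0 * sum(min(pa.get(k, 0.0), pb.get(k, 0.0))
                       for k in set(pa) | set(pb))


def overlap_oracle_study(n_pairs: int = 100, seed: int = 0) -> dict:
    """Agreement of distribution_overlap with the brute-force oracle."""
    rng = np.random.default_rng(seed)
    diffs = []
    for _ in range(n_pairs):
        n1, n2 = rng.integers(5, 200, 2)
        mu1, mu2 = rng.uniform(-1.0, 1.5, 2)
        a = rng.lognormal(mu1, rng.uniform(0.2, 0.8), n1)
        b = rng.lognormal(mu2, rng.uniform(0.2, 0.8), n2)
        bw = float(rng.uniform(0.02, 0.5))
        diffs.append(abs(evt.distribution_overlap(a, b, bw)
                         - overlap_bruteforce(a, b, bw)))
    return {"max_abs_diff": float(np.max(diffs)),
            "mean_abs_diff": float(np.mean(diffs))}


# ---------------------------------------------------------------------------
# behavioral recovery
# ---------------------------------------------------------------------------

def _paired_protocol(n_trials: int, cs_onset: float = 3.0,
                     cs_duration: float = 2.0,
                     sweep: float = 6.5) -> List[TrialProtocol]:
    off = cs_onset + cs_duration
    return [TrialProtocol(i + 1, "paired", cs_onset, off, off, None, sweep)
            for i in range(n_trials)]


def behavior_study(n_sessions: int = 200, n_trials: int = 70,
                   acquisition_trial: int = 28, plateau: float = 0.59,
                   learner: bool = True, seed: int = 0) -> dict:
    """Learner flagging and acquisition-trial recovery on planned behavior.

    Scores ground-truth episode plans directly (no trace rendering), which
    isolates the scoring logic from burst detection.
    """
    protocol = _paired_protocol(n_trials)
    model = LearnerModel(is_learner=learner,
                         acquisition_trial=acquisition_trial,
                         plateau_cr_prob=plateau)
    roots = np.random.SeedSequence(seed).spawn(n_sessions)
    flags, acq_detected = [], []
    for r in roots:
        rng = np.random.default_rng(r)
        outcomes = []
        n_crs = 0
        for p in protocol:
            plan = behavior_model(model, p, rng, n_prior_crs=n_crs)
            if plan.cr:
                n_crs += 1
            sw = [SwimEpisode(e.onset, e.offset, list(e.burst_times))
                  for e in plan_to_episodes(plan, p)]
            outcomes.append(bhv.classify_trial(sw, p))
        flags.append(bhv.learner_flag(outcomes))
        acq_detected.append(bhv.acquisition_trial(outcomes))
    found = [a for a in acq_detected if a is not None]
    return {
        "learner_flag_rate": float(np.mean(flags)),
        "median_detected_acquisition": float(np.median(found))
        if found else float("nan"),
        "median_abs_acquisition_error": float(np.median(
            [abs(a - acquisition_trial) for a in found]))
        if found else float("nan"),
        "fraction_with_acquisition": len(found) / n_sessions,
    }


# ---------------------------------------------------------------------------
# cell-class recovery
# ---------------------------------------------------------------------------

def _count_trend(counts: pd.DataFrame) -> float:
    """Late-third minus early-third mean count across a session."""
    c = counts.sort_values("trial_index")["count"].to_numpy(float)
    k = max(len(c) // 3, 1)
    return float(np.mean(c[-k:]) - np.mean(c[:k]))


def classification_study(n_per_class: int = 10, n_pseudo: int = 6,
                         n_trials: int = 24, acquisition_trial: int = 12,
                         seed: int = 0) -> dict:
    """MCS/SCS/ZCS recovery on full simulated sessions through the pipeline.

    Sessions are trace-level: events are re-detected from the simulated
    membrane potential and CRs from the simulated ventral root before the
    classifier runs.  Also measures the early-to-late trend of CS-window
    complex-spike counts (MCS template) and pfEPSP counts (ZCS template),
    with pseudoconditioned sessions as the no-learning contrast.
    """
    roots = np.random.SeedSequence(seed).spawn(3 * n_per_class + n_pseudo)
    confusion: Dict[str, Dict[str, int]] = {}
    trends: Dict[str, List[float]] = {"MCS": [], "ZCS_pf": [], "pseudo": []}
    n_labeled = n_correct = 0
    idx = 0
    for true_label in ("MCS", "SCS", "ZCS"):
        for _ in range(n_per_class):
            s = int(roots[idx].generate_state(1)[0] % (2 ** 31))
            idx += 1
            cfg = SessionConfig(
                cell=CellSimConfig(class_label=true_label),
                learner=LearnerModel(acquisition_trial=acquisition_trial),
                n_paired=n_trials)
            bundle = simulate_session(cfg, s)
            events = detect_session_events(bundle)
            outcomes, _ = score_session_swim(bundle)
            if not any(o.cr_present for o in outcomes):
                continue
            res = cls.classify_cell(events, outcomes, bundle.protocol)
            n_labeled += 1
            n_correct += res.label == true_label
            confusion.setdefault(true_label, {}).setdefault(res.label, 0)
            confusion[true_label][res.label] += 1
            acq = bhv.acquisition_trial(outcomes) or acquisition_trial
            if true_label == "MCS":
                trends["MCS"].append(_count_trend(cls.cs_window_counts(
                    events, bundle.protocol, align_trial=acq)))
            if true_label == "ZCS":
                trends["ZCS_pf"].append(_count_trend(cls.pf_count_during_cs(
                    events, bundle.protocol, align_trial=acq)))
    for _ in range(n_pseudo):
        s = int(roots[idx].generate_state(1)[0] % (2 ** 31))
        idx += 1
        cfg = SessionConfig(
            cell=CellSimConfig(class_label="MCS"),
            learner=LearnerModel(is_learner=False, plateau_cr_prob=0.05),
            n_paired=n_trials, pseudo=True)
        bundle = simulate_session(cfg, s)
        events = detect_session_events(bundle)
        trends["pseudo"].append(_count_trend(cls.cs_window_counts(
            events, bundle.protocol, align_trial=10)))
    return {
        "n_labeled": n_labeled,
        "accuracy": n_correct / n_labeled if n_labeled else float("nan"),
        "confusion": confusion,
        "mcs_cs_count_trend": float(np.mean(trends["MCS"]))
        if trends["MCS"] else float("nan"),
        "zcs_pf_count_trend": float(np.mean(trends["ZCS_pf"]))
        if trends["ZCS_pf"] else float("nan"),
        "pseudo_cs_count_trend": float(np.mean(trends["pseudo"]))
        if trends["pseudo"] else float("nan"),
    }


# ---------------------------------------------------------------------------
# optogenetic suppression
# ---------------------------------------------------------------------------

def arch_study(n_trials: int = 60, seed: int = 0) -> dict:
    """Detected firing rates inside vs outside the illumination window.

    Simple-spike rates should collapse under the outward pump current while
    complex-spike rates persist.  Rates are basal: the session uses no
    stimulus-evoked climbing-fiber responses, matching how the on/off
    comparison is made (spontaneous firing with and without illumination).
    """
    from .synthetic import ClassTemplate

    cfg = SessionConfig(
        cell=CellSimConfig(class_label="untrained"),
        learner=LearnerModel(is_learner=False, plateau_cr_prob=0.05),
        template=ClassTemplate(us_cxs_prob={}),
        n_paired=n_trials, arch=True)
    bundle = simulate_session(cfg, seed)
    events = detect_session_events(bundle)
    proto = {p.trial_index: p for p in bundle.protocol}
    t_in = t_out = 0.0
    n_in = {"complex": 0, "simple": 0}
    n_out = {"complex": 0, "simple": 0}
    for p in bundle.protocol:
        lo, hi = p.illumination_window
        t_in += hi - lo
        t_out += p.sweep_duration - (hi - lo)
    for r in events.itertuples(index=False):
        if r.label not in n_in:
            continue
        lo, hi = proto[r.trial_index].illumination_window
        if lo <= r.time_s < hi:
            n_in[r.label] += 1
        else:
            n_out[r.label] += 1
    rates = {
        "simple_rate_illuminated": n_in["simple"] / t_in,
        "simple_rate_baseline": n_out["simple"] / t_out,
        "complex_rate_illuminated": n_in["complex"] / t_in,
        "complex_rate_baseline": n_out["complex"] / t_out,
    }
    rates["simple_suppression_ratio"] = (
        rates["simple_rate_illuminated"] / rates["simple_rate_baseline"]
        if rates["simple_rate_baseline"] else float("nan"))
    rates["complex_rate_change"] = (
        abs(rates["complex_rate_illuminated"] - rates["complex_rate_baseline"])
        / rates["complex_rate_baseline"]
        if rates["complex_rate_baseline"] else float("nan"))
    return rates
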