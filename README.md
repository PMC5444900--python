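# swimsort

Analysis pipeline for classical-conditioning experiments in larval
zebrafish with simultaneous Purkinje-cell whole-cell and ventral-root
recordings — plus a conductance-based simulator that generates complete
synthetic sessions with exact ground truth, so every stage of the analysis
can be validated quantitatively.

## What it does

**Intracellular event sorting.** Current-clamp recordings from immature
Purkinje cells contain three event types that differ in their rate of
rise: complex spikes (giant climbing-fiber EPSPs), simple spikes (small Na
action potentials with an EPSP foot on the upstroke), and parallel-fiber
EPSPs whose summation produces long-lasting depolarizations. `swimsort`
sorts them with a three-stage dV/dt threshold cascade (defaults 20 / 8 /
0.4 mV/ms, each stage run on the residual record after the previous
stage's events are masked) and validates each event by the conductance
underlying its upstroke,

    g = C · (dV/dt)_peak / (E_rev − V)        [pF · mV/ms / mV = nS],

with explicit, configurable surrogates for the classical by-eye checks:
a baseline-rise test, amplitude and sustained-depolarization gates for
complex spikes, an EPSP-foot gate for simple spikes, and a waveform gate
for pfEPSPs. Conductances are normalized per cell to the mean
complex-spike conductance, and histogram overlap coefficients
(100 · Σ min(pᵢ, qᵢ) on a shared binning) quantify class separation.

**Fictive-swim scoring.** Ventral-root recordings are rectified, smoothed
(2 ms), and thresholded relative to a quiet baseline to find motor bursts;
bursts group into swim episodes; episodes are scored per trial as
conditional responses (CR: onset inside the CS window before the US),
unconditional responses (UR: shortly after the US), or spontaneous.
Session statistics include the learner criterion (> 20 % CRs), the
acquisition trial (first run of consecutive CRs), extinction under
CS-alone trials, per-block CR percentages, and CR-property trajectories
(latency, bursts/episode, burst frequency).

**Cell classification.** After learning, cells are labeled by their
CR-associated complex spiking: MCS (two or more per CR on most trials),
SCS (one), ZCS (none, with parallel-fiber drive instead), using a padded
window around the swim episode. Supporting statistics cover CS-window
complex-spike counts aligned to acquisition, latency means and CVs,
complex-spike probability near CR onset/offset, pfEPSP counts during the
CS, and the lag of long depolarizations relative to swimming.

**Simulation.** A single-compartment membrane
(C dV/dt = −g_leak(V−E_leak) − Σ gᵢ(t)(V−Eᵢ) + I) driven by biexponential
synaptic conductances reproduces the statistical structure of the
recordings: lognormal conductance amplitudes (4.86 / 1.17 / 0.17 nS for
cf / ss / pf events), Poisson basal firing (0.3 and 6.4 events/s),
learner and non-learner behavioral trajectories, class-specific event
templates, and an optogenetic mode in which an 18.6 pA outward pump
current suppresses simple but not complex spikes during illumination.

## Worked example

```python
from swimsort import (RunConfig, SessionConfig, CellSimConfig,
                      LearnerModel, run_full_session)

config = RunConfig(
    seed=0,
    session=SessionConfig(
        cell=CellSimConfig(class_label="MCS"),
        learner=LearnerModel(acquisition_trial=8),
        n_paired=20))
report = run_full_session(config, out_dir="out")
```

This simulates a 20-trial conditioning session for a multiple-complex-
spike cell whose fish acquires CRs around trial 8, re-detects everything
from the raw traces, and prints (via the report):

```
learner: True
CR percent: 50.0
acquisition trial: 7
cell label: MCS
CR-window complex-spike counts: [3, 2, 1, 3, 2, 1, 3, 2, 2, 3]
complex F1 vs ground truth: 0.978
simple F1 vs ground truth: 0.983
pfEPSP F1 vs ground truth: 0.727
CR trial agreement: 0.95
```

The fish produced CRs on 50 % of trials (a learner), the first run of
consecutive CRs began at trial 7, and the cell is labeled MCS because a
majority of its CR trials carry two or more detected complex spikes. The
F1 scores compare re-detected events against the simulator's exact event
list; pfEPSP recall is deliberately conservative (the sorting criteria
trade missed small EPSPs for a low false-positive rate).

The same stages are available from a shell:

```
swimsort simulate --seed 1 --out session/
swimsort detect --bundle session/ --out events.csv
swimsort swim --bundle session/ --out episodes.csv
swimsort score --bundle session/ --out summary.json
swimsort run-all --seed 1 --out out/
```

## Layout

- `swimsort.synthetic` — session simulator and behavioral model
- `swimsort.io` — session bundles (CSV/JSON), event tables, HDF5 export
- `swimsort.events` — the dV/dt cascade, conductance estimation, overlap,
  long depolarizations and hyperpolarizations
- `swimsort.swim` — ventral-root envelope, bursts, episodes
- `swimsort.behavior` — CR/UR scoring and session summaries
- `swimsort.classify` — cell classes and CR-locked statistics
- `swimsort.pipeline` — end-to-end runs, ground-truth comparison
- `swimsort.studies` — cohort-scale validation studies
- `docs/methods.md` — model and design notes
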