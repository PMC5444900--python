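# Methods

## The membrane model

Every simulated sweep integrates a single-compartment conductance model

    C dV/dt = −g_leak (V − E_leak) − Σᵢ gᵢ(t) (V − Eᵢ) + I_applied

with an exponential-Euler step (exact when conductances are held constant
over one sample). Defaults: C = 10.7 pF (the measured mean capacitance of
these cells), g_leak = 0.7 nS, E_leak = −60 mV. The leak value is pinned
by the optogenetic observations: an 18.6 pA outward pump current
hyperpolarizes the model by 26.6 mV, matching the reported ~27 mV. The
resulting membrane time constant (~15 ms) is what lets small
parallel-fiber EPSPs (~3 mV, fast synaptic decay) summate into
long-lasting depolarizations at input rates of tens of Hz. Reversal
potentials are fixed at E_exc = 0, E_Na = +55, E_inh = −75 mV; none is
stated for the original preparation, and these are standard values whose
exact choice only rescales conductances by a few percent.

Synaptic events are biexponential conductance transients (rise/decay, ms):
climbing fiber 0.3/3.0, parallel fiber 0.8/3.0. A simple spike is a
stereotyped waveform: a fixed 0.3 nS EPSP foot starting 2 ms before the
regenerative onset, a fast Na-like conductance (0.25/1.2 ms) whose peak is
the drawn "upstroke conductance", and a delayed 2.5 nS repolarizing
conductance. The analysis consumes only the upstroke shape, so no
Hodgkin–Huxley machinery is modeled. Hyperpolarizing responses are slow
inhibitory envelopes (50/250 ms) with amplitudes giving 5–10 mV
deflections.

### Event statistics

Conductance amplitudes are lognormal on the natural scale, matched to the
reported mean ± SD: 4.86 ± 0.25 nS (climbing fiber), 1.17 ± 0.5 nS
(simple-spike upstroke), 0.17 ± 0.08 nS (parallel fiber). Lognormal
(rather than Gaussian) because the distributions are positive and
right-skewed. Basal event times are homogeneous Poisson at 0.3 /s
(complex) and 6.4 /s (simple); the basal parallel-fiber rate is not
reported and is set to 8 /s from the ratio of pfEPSPs to simple spikes in
the pooled event catalogue (~21 000 vs ~17 000).

Two deliberate departures from naive sampling:

- **Regenerative floor.** The printed simple-spike conductance SD
  (0.5 nS) together with the 8 mV/ms detection threshold would imply that
  ~20 % of simple spikes rise too slowly to be spikes at all, contradicting
  the tight printed upstroke spread (10.5 ± 0.6 mV/ms). Spikes are
  all-or-none: draws below a 0.9 nS floor are treated as failures and
  redrawn.
- **Event displacement, not deletion.** Minimum separations (8 ms between
  simple spikes; a ±15 ms complex-spike pause; 20 ms between climbing-fiber
  events, 60 ms for CR-locked template events since olivary firing stays
  well below ~15 Hz) are enforced by moving events, so programmed Poisson
  counts are preserved exactly — a property the tests check to 3 standard
  errors.

The simulation grid is 10 kHz by default (configurable up to 50 kHz);
all thresholds are in mV/ms so results are rate-independent above 10 kHz,
and rates below 10 kHz are rejected because they cannot resolve a 1 ms
conductance rise.

## Behavioral model

A fish is a `LearnerModel`: CR probability is 0.04 before acquisition,
ramps linearly over the five trials leading up to the programmed
acquisition trial, and sits at the 0.59 plateau from it on (the ramp ends
at acquisition so that the first run of consecutive CRs lands at the
programmed trial in the median). CS-alone trials multiply the probability
by 0.5 per consecutive presentation. CR properties interpolate from their
initial values (latency 1.1 s, 7.2 bursts, 23 Hz — the reported initial-CR
statistics) to plateau values over the first five CR-bearing trials; the
plateau values (0.85 s, 10 bursts, 25 Hz) are not reported numerically and
were chosen once to reproduce the reported direction and rough magnitude
of each trend. The US elicits a UR with full reliability at 16.9 ± 3 ms.
With the prescribed extinction decay and a 3-consecutive-non-CR stopping
rule, the median trials-to-extinction of the model is ~1–2 (direct
enumeration of the binomial process); the tests therefore assert agreement
with an independent simulation of that process rather than any fixed
count.

Class templates add episode-locked events: MCS cells fire 2–3 climbing-
fiber events spread across each CR plus CS-locked events whose expectation
grows with training; SCS cells fire exactly one, at −74 ± 30 ms from CR
onset (p ≈ 0.76) or +223 ± 28 ms after CR offset; ZCS cells fire none
during CRs (their basal climbing-fiber events are gated out of the padded
CR window — the class definition is incompatible with movement-independent
Poisson input) but receive a 100 Hz parallel-fiber barrage starting 171 ms
before CR onset and a CS-locked pfEPSP rate that ramps with training.
Non-learning (pseudoconditioned) sessions keep every template flat.

## The detection cascade

Derivatives are local linear-regression slopes (Savitzky–Golay, order 1):
0.2 ms windows for the spike stages and 1 ms for the pfEPSP stage, where
the 0.4 mV/ms threshold would otherwise be dominated by noise (for 0.2 mV
recording noise the 0.2 ms-window slope SD is ~1.4 mV/ms; 1 ms brings it
to ~0.19).

Stage 1 (complex spikes) thresholds the driving-force-normalized
derivative — equivalent to the plain 20 mV/ms rule at rest but
compensating on depolarized plateaus, where the same climbing-fiber
conductance produces a slower rise (this is the "conductance underlying
the upstroke" check applied up front). Candidates must rise directly from
the local baseline: the onset, found by walking back on the smooth
derivative, must be reached within 1.2 ms of the crossing; the mean slope
over the 2 ms before onset must stay below 4 mV/ms; the onset voltage must
sit within 6 mV of the preceding 50 ms median; the event must depolarize
by ≥ 20 mV; and the membrane must remain ≥ 8 mV above onset throughout
2–12 ms after the crossing. The last gate is the decisive one against the
largest simple spikes: a giant EPSC keeps the cell depolarized for tens of
milliseconds, while an actively repolarized spike is back near baseline
within a few (measured separation ~30 mV vs ~1 mV). Near-coincident
crossings (secondary humps) merge within 2 ms. A conductance floor —
2 SD above the cell's pooled simple-spike mean — demotes residual
low-conductance events in a second pass once simple-spike statistics
exist; cells with no simple spikes skip the floor and are flagged.

Stage 2 (simple spikes) masks complex-spike spans and thresholds at
8 mV/ms; each crossing must carry the EPSP-foot signature, implemented as
the mean pre-crossing slope lying between θ_pf/2 and θ_simple — a
depolarizing but sub-threshold foot, the complement of the complex-spike
baseline-rise test. (The raw-derivative dip sketch of an inflection is
noise-dominated at 10 kHz and was replaced by this gate; both are
validated only against simulator ground truth.)

Stage 3 (pfEPSPs) masks all spikes — each simple spike through its
afterhyperpolarization, adaptively until the voltage recovers to the
pre-spike baseline, plus any unlabeled fast transient — and accepts
sustained runs of the slow derivative above 0.4 mV/ms whose waveform is
EPSP-like: a monophasic rise of ≥ 1 mV peaking within 12 ms, a decay to
half amplitude within 50 ms unless a later event summates onto it, an
onset below the cell's empirical simple-spike threshold voltage, and no
rebound out of a preceding trough. Look-ahead windows stop at the next
masked sample so a following spike cannot vouch for a candidate.
Candidates within 15 ms of an accepted event are duplicates of the same
rise and dropped. The criteria are intentionally stringent: missed small
or spike-adjacent EPSPs are accepted in exchange for precision.

Long depolarizations are runs where the spike-removed, 20 ms
median-filtered voltage stays ≥ 2 mV above the pre-trial baseline median
(sub-50 ms dips tolerated) for ≥ 200 ms, onset assigned to the earliest
pfEPSP within 50 ms before the rise. Hyperpolarizations are ≥ 100 ms runs
below the most negative pre-trial voltage of the filtered trace. An
optional noise-adaptive mode scales thresholds to k × SD of baseline
dV/dt; fixed thresholds are the default and the validated mode.

## Ventral root and behavior scoring

The envelope is the rectified signal smoothed by a centered 2 ms moving
average. Bursts are maximal supra-threshold runs (baseline mean + 4 SD) at
least 1 ms long, merged within 5 ms, with onsets refined by walking back
to where the envelope left the baseline band; a ±2 ms blanking window
removes the US stimulation artifact. Bursts within 200 ms share an
episode; burst frequency is (n − 1)/duration. The 4 SD and 200 ms values
are not reported in the original work; they were chosen so simulated
inter-burst intervals (13–45 ms) never split an episode while distinct
bouts never merge, and both are config keys.

Windows are half-open [start, end). A CR is an episode starting in
[cs_onset, us_time); on CS-alone trials the window extends 300 ms past the
CS offset (offset swimming counts when no US truncates the trial). A UR
starts within 100 ms after the US. Acquisition is the first trial of the
earliest run of ≥ 2 consecutive CR trials; extinction counts CS-alone
trials before the first 3 consecutive non-CR trials; the learner criterion
is strictly > 20 % CRs over CS-bearing trials.

## Cell classification

"During the CR" is the padded interval from 150 ms before episode onset to
300 ms after offset, because CR-associated climbing-fiber events lead the
onset (−74 ms) or trail the offset (+223 ms). ZCS requires zero complex
spikes on every CR trial; MCS requires a strict majority of CR trials with
≥ 2 (ties resolve to SCS, against the stronger claim); SCS is the
remainder. Latency CVs are SD/|mean| across trials and are flagged
undefined when |mean| < 10 ms (the ratio diverges); CS-window counts are
re-indexed to the acquisition trial (tenth trial for pseudoconditioned
sessions, the cohort's median).

## What the simulator does and does not establish

The synthetic sessions reproduce the event amplitudes, rates, behavioral
statistics, and class structure that the analyses consume — with known
ground truth, which real recordings never have. They do not reproduce
electrode drift, seal changes, cell-to-cell kinetic differences,
movement artifacts on the intracellular channel, or genuinely ambiguous
intermediate events; passing the recovery suites therefore demonstrates
the internal consistency and correctness of the pipeline under the
modeled statistics, not field performance on arbitrary recordings. The
validation cohorts use per-cell synaptic scale factors clipped to the
range where the fixed thresholds apply (quieter cells are what the
adaptive mode is for); headline numbers from the original recordings that
depend on the actual cell sample (class counts, the 15.2 % absolute
overlap) are not reproduction targets, though the qualitative ordering —
pooled absolute overlap exceeding pooled normalized overlap exceeding
within-cell overlap — is.

## Problem sizes and determinism

The validation studies use 50 ten-second basal sweeps (detection and
normalization), 200 sessions × 70 trials (behavior, scored at the
episode-plan level to isolate the scoring logic), 30 template cells × 24
trials simulated and re-detected at full trace level plus 6
pseudoconditioned sessions (classification), and 60 illumination trials
(optogenetic suppression). Every random draw descends from a single seed
through `numpy.random.SeedSequence`; identical configs and seeds
reproduce sessions bit-for-bit and pipeline outputs byte-for-byte, and
every JSON output embeds the SHA-256 hash of its run configuration.
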