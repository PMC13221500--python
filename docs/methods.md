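# Methods

## Scope and model overview

`volstop` simulates a closed-loop volitional stop-signal (GO/NO-GO)
neurofeedback task and its photometry/behavior analysis. Three things are
modelled: (1) region-wise fluorescence signals as baseline plus Gaussian
noise plus stereotyped event-locked transients; (2) a trained mouse as a
small set of per-trial probabilities and latencies; (3) chemogenetic and
optogenetic perturbations as multiplicative effects on those two models.
Everything downstream — threshold detection, trial state machine, ΔF/F
processing, peak extraction, group statistics — operates only on the
simulated signals and logs, exactly as the corresponding analysis would
operate on recorded data.

## Transient kernels and region profiles

Each event class (GO cue, stop cue, feedback, reward, volitional ramp)
contributes a difference-of-exponentials transient

    k(t) = A · (exp(−t/τ_d) − exp(−t/τ_r)) / norm,   t ≥ 0,

peak-normalized so max k = A (ΔF/F units against a region baseline of
1 a.u.). The family gives the fast-rise/slow-decay shape of genetically
encoded calcium indicators; k(0) = 0 and k → 0.

Published traces for this paradigm are shown unscaled, so amplitudes and
time constants are free parameters. Defaults were chosen once for clear
temporal separation of the components (window cross-talk below 10 %, see
"Peak windows"):

| region | go_cue | stop_cue | volitional | feedback | reward | noise SD |
|--------|--------|----------|------------|----------|--------|----------|
| M1     | 0.05   | 0 (absent) | 0.08     | 1.0      | 1.0    | 0.002    |
| GPe    | 0.5    | 0.3      | 0.08       | 1.0      | 0.8    | 0.002    |
| STN    | 0.5    | 0.3      | 0.08       | 1.0      | 0.9    | 0.002    |

τ_r/τ_d (s): cues 0.05/0.3, feedback 0.08/0.3, reward 0.2/0.6, volitional
ramp 0.4/0.8. The stop-cue response is absent in M1 and present in the
basal-ganglia regions; auditory-cue responses in M1 are kept below the
feedback threshold so cue playback cannot trip the loop. Noise is i.i.d.
Gaussian on fluorescence at 100 Hz; no photobleaching drift by default (a
linear-drift flag exists but the analysis chain does no detrending).

## Agent model

Per-trial behavior of a trained animal:

* `p_go_success = 0.9` — probability of attempting (and, by construction,
  achieving) a GO crossing; attempt latency ~ Normal(4.0, 1.5) s, clipped
  to [1, 27] s so the crossing stays inside the 30-s window.
* `p_inhibit = 0.75` — probability of withholding through the NO-GO hold.
  Lower than the single-task training criterion (0.85) because the mixed
  task makes the prepotent GO response harder to cancel.
* `premature_rate = 0.01` — probability of a crossing before the stop cue;
  kept small so the error-trial response-time distribution (a mixture of
  premature and post-stop crossings) stays comparable across groups whose
  `p_inhibit` differs.
* `lick_rate = 5 /s` within 2-s post-reward bouts (homogeneous Poisson).

## Threshold and the decision signal

The engine monitors a causal (trailing) 0.5-s moving average of the M1
ΔF/F signal on the 100-Hz simulation grid and fires at the first sample at
or above threshold (a one-sample decision latency is accepted; the 30-s GO
boundary is inclusive). The smoothing is what makes a sample-wise threshold
usable: on raw 100-Hz ΔF/F any threshold near baseline + 2 SD is crossed
by noise alone with near-certainty over a 30-s window (≈2.3 % per sample).

The default threshold is a **fixed ΔF/F value of 0.06** — above the
smoothed cue-evoked response (≈0.02 in M1) and below the smoothed
volitional-ramp plateau (≈0.074), so cue playback never triggers feedback
and an attempted ramp always does. A `baseline mean + k·SD` rule over a
pre-session baseline block is implemented and selectable, but it is not the
default: with deterministic cue-evoked transients in the signal, a
noise-statistics threshold either sits below the cue response (false
triggers on every trial) or must be tuned per profile anyway.

## Closed-loop rendering and the fast path

Each trial is rendered in two passes with one shared noise draw: a
detection pass (baseline + noise + cue + planned volitional ramp) on which
the threshold detector runs, then a final pass that adds the transients of
whatever events the detector caused (feedback, reward). Withdrawal variants
omit an event from both the log and the generator, so the corresponding
transient vanishes — the component arrays returned alongside each trace
reconstruct it exactly (trace = baseline + noise + Σ components).

A behavior-only fast path (`synth_traces=False`) skips rendering and places
the crossing at ramp onset plus a precomputed noiseless detector offset.
Because the threshold sits ~14 smoothed-noise SDs above baseline, noise
neither creates nor prevents crossings; seed-matched outcomes agree between
paths, with response times within a few 10-ms samples (the residual jitter
comes from noise in the two-sample F0 baseline). The statistical suites
(calibration, pattern recovery) use this path at full session size.

## Manipulation effect tables

Effects are multiplicative; directions encode the reported contrasts, and
magnitudes were fixed by design-stage power analysis (before any validation
suite was run) so that each programmed effect is recoverable at the study's
group sizes and each programmed null stays null:

* **hM3D** (excitatory DREADD in M2-innervated GPe): `p_go_success` ×0.6;
  NO-GO failure rate ÷2.5; `lick_rate` ×0.7; GPe feedback-kernel gain ×0.5.
* **hM4D** (inhibitory DREADD): behavior unchanged; M1 reward gain ×0.6,
  STN feedback gain ×0.5, GPe feedback gain ×0.6.
* **eNpHR at feedback**: `p_go_success` ×0.7; GO latency ×1.3; NO-GO
  failure rate ÷2.0; STN feedback and reward gains ×0.5 inside a 1-s
  window locked to the affected event.
* **eNpHR at cue**: no behavioral or signal effects (the reported null).
* **eNpHR at reward**: behavior unchanged; STN volitional/feedback/reward
  gains ×0.6 inside the 1-s window.

Inhibition effects act on the NO-GO *failure rate* rather than multiplying
`p_inhibit` directly: a probability multiplied upward saturates at 1, which
would leave the manipulated groups without error trials and make the
error-trial response-time comparisons (reported as null) untestable.
Optogenetic gains are event-locked: each affected component is scaled only
within 1 s of its own event, mirroring time-locked illumination.

## Photometry processing

* **Smoothing**: 20-ms centered moving average stepped every 10 ms; edge
  windows are truncated, not padded (documented so outputs are stable).
* **ΔF/F**: F0 is the mean fluorescence in a 10-ms cue-locked window. The
  `compute_dff` primitive places the window wherever asked; the session
  pipeline anchors it to the 10 ms immediately *preceding* cue onset
  (ending one smoothing half-span before the cue). A window following cue
  onset is contaminated by the rising cue transient — kernels rise linearly
  from the event, so 10 ms into a GPe cue response is already ~15 % of its
  peak — which would bias every peak in cue-responsive regions.
* **Alignment**: trials are aligned to reward delivery (15 s pre / 10 s
  post by default; 10/10 is used for the optogenetic figures' convention),
  falling back to feedback, crossing, then cue when the reward is absent
  (withdrawal variants keep their would-be anchor times in the ground-truth
  sidecar). Truncated segments are flagged.
* **Peak windows** (relative to the anchoring event): cues and feedback
  [0, +1] s; reward [0, +3] s; volitional [−2, −0.05] s before the
  threshold crossing. The volitional window stops 50 ms short of the
  crossing because the centered smoother blends the feedback-tone onset
  into the boundary sample. With the default kernels, residual cross-talk
  between windows is below 10 %, and the windows-based peaks match the
  generator's per-component ground truth within 10 % on ≥95 % of
  measurements; the remaining misses are genuine overlap (e.g. the stop-cue
  response inside GPe/STN volitional windows on early NO-GO errors).

## Behavioral statistics

* Success rates are successes/presented per trial type; response time is
  trial onset to threshold crossing (NO-GO response times exist on error
  trials only). Premature NO-GO crossings are scored as failures, carry
  their response time, and are flagged in the log so alternative scoring
  can be applied.
* "Total licks" is counted per session across both trial types: every
  session delivers the same number of rewards (the success target), so the
  count isolates lick-rate effects and is not confounded by shifts in the
  GO/NO-GO success mix.
* Endpoints are averaged across a mouse's included sessions first (the
  three CNO-on days in the chemogenetic design; all days otherwise), giving
  one independent point per mouse.
* Student's *t* uses pooled variance (Welch is available through scipy
  directly); zero pooled variance with equal means returns t=0, p=1, with
  unequal means a flagged degenerate result. Mann-Whitney *U* reports the
  smaller of U_a/U_b with an exact two-tailed p for combined n ≤ 16 without
  ties and a tie-corrected normal approximation otherwise. No
  multiple-testing correction is applied (per-comparison p-values only).
  The file-based report runs both tests and flags endpoints where they
  disagree at 0.05.

## Validation suites and problem sizes

* **Type-I calibration**: 1000 null experiments (two control groups, n=6
  vs 6, one 50-success session per mouse); both tests reject within
  0.05 ± 3·SE.
* **Withdrawal detection**: 100 replicates, n=6 vs 6, traced GO-only
  sessions of 12 successes; the withdrawn component's per-mouse mean peak
  is detected at p < 0.05 in ≥80 % (empirically ~100 %) of replicates.
* **Pattern recovery**: 100 replicates of the full chemogenetic and three
  optogenetic designs at study sizes (6/6/6 and 6/7 mice, 6- and 3-day
  designs, 50-success sessions, behavior-only); each expected
  significant/null cell of the result matrix is scored per replicate and
  must be correct in ≥80 %. Null cells sit near the 5 % false-positive
  floor; effect cells near 100 % power.

## What the generator does and does not emulate

It emulates: event-locked transient structure across three regions,
closed-loop contingency between signal and events, session composition and
termination, lick bouts, group structure, and manipulation contrasts with
known ground truth. It does not emulate: biophysical or spiking dynamics,
learning across days (training is a parameter preset; the 85 %-over-three-
days criterion is implemented as a filter, not an acquisition model),
photobleaching or motion artifacts, hemodynamic/isosbestic confounds, or
hardware latencies. Passing tests therefore demonstrate that the analysis
chain is correct and well calibrated on data satisfying its assumptions —
not that those assumptions hold for any particular recording.

## Numerical conventions and degenerate cases

Simulation and decisions share a 100-Hz grid; event times are grid-aligned
and float comparisons use 1-ns tolerances. A GO crossing exactly at the
30-s boundary counts as success. Failed NO-GO trials abort at the crossing;
failed GO trials run out the 30-s window. Failure adds no timeout beyond
the standard ITI. The random-reward test co-plays the GO cue with rewards
decoupled from the signal. Scripted-agent crossings are placed by inverting
the noiseless detector offset and are exact on the grid when the ramp does
not overlap cue-evoked transients; overlapping placements (e.g. a scripted
premature crossing at 1 s) land within ~0.1 s. Sessions that hit the
500-trial safety cap before reaching 50 successes are flagged rather than
failed. Unknown config keys, unknown event classes, empty detection
windows, non-positive baselines, and undefined rates (zero presented
trials) all raise typed errors.
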