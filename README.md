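# volstop

Simulation and analysis of a closed-loop **volitional stop-signal task**: a
brain-computer-interface paradigm in which a head-fixed mouse learns to
drive (GO) or suppress (NO-GO) the population calcium signal of its primary
motor cortex (M1), recorded by fiber photometry, relative to a threshold
that gates auditory feedback and a sucrose reward.

The package is for computational neuroscientists who want to prototype or
validate the analysis chain of such closed-loop neurofeedback experiments
without animals: a parametric mouse agent generates multi-region calcium
traces (M1 under GCaMP6f; GPe and STN under jRGECO1a), the task engine runs
the closed loop against them, and the photometry/statistics stages recover
the programmed ground truth.

## The paradigm

* **GO trial** — a 5,000-Hz cue; the mouse must push the M1 ΔF/F signal
  above threshold within 30 s. The crossing triggers a 10,000-Hz feedback
  tone (500 ms), and the reward follows 1 s after feedback onset.
* **NO-GO trial** — the GO cue followed 2 s later by a 27,000-Hz stop cue;
  the signal must stay below threshold for 13 s, after which feedback and
  (1 s later) reward are delivered. Any crossing fails the trial.
* Trials are drawn randomly (67 % GO / 33 % NO-GO), separated by a 10-s
  inter-trial interval; a session ends after 50 successful trials.

The closed loop is literal: feedback is emitted iff the threshold detector
fires on the synthesized, noise-bearing M1 ΔF/F signal, and the resulting
events are fed back into the generator so the corresponding calcium
transients appear in — or, in withdrawal variants, vanish from — the
rendered traces.

## The analysis chain

Fluorescence traces are smoothed with a 20-ms moving-average filter stepped
every 10 ms and converted to **ΔF/F = (F − F0)/F0** with F0 a cue-locked
baseline. Trials are aligned to reward delivery (15 s before / 10 s after),
and per-component peaks — GO cue, stop cue, volitional ramp, feedback,
reward — are extracted in event-locked windows. Behavioral endpoints
(success rates per trial type, response times, lick counts) are averaged
across sessions per mouse, and each manipulation group is compared with its
control by an unpaired two-tailed Student's *t* test (pooled variance) and
a Mann-Whitney *U* test (exact for small untied samples).

Chemogenetic (hM3D/hM4D, CNO on alternate days of a 6-day design, n=6/6/6)
and optogenetic (eNpHR, 1-s suppression locked to feedback, cue, or reward;
n=6 vs 7) manipulations are modelled as multiplicative effects on agent
parameters and on transient-kernel gains, giving the pipeline recoverable
ground truth.

## Worked example

Simulate a 10-success session and inspect it:

```
$ volstop simulate --seed 7 --n-success 10 --out scratch/demo
mouse=m0 trials=12 successes=10 (GO 8/10, NOGO 2/2) licks=105 threshold=0.0600 out=scratch/demo
```

The session presented 12 trials to collect 10 successes (8 of 10 GO trials
succeeded, both NO-GO trials were correctly withheld), produced 105 reward
licks, and used the default fixed ΔF/F threshold of 0.06. The directory now
holds the flat event log (CSV), the three-region trace file, a ground-truth
sidecar, and a config snapshot; `volstop analyze scratch/demo` adds the
component-peak table and a statistics report.

A full chemogenetic experiment, compared in memory:

```python
from volstop.engine import run_experiment
from volstop.experiments import summarize_and_compare

expt = run_experiment("chemogenetic", 11, synth_traces=False)
c = summarize_and_compare(expt, "go_success")["hM3D"]
print(f"hM3D GO success: {c.mean_a:.3f} vs control {c.mean_b:.3f}, "
      f"t={c.statistic:.2f}, p={c.p_value:.4g} {c.stars}")
```

prints

```
hM3D GO success: 0.543 vs control 0.891, t=-18.83, p=3.87e-09 ***
```

— activating the modelled GPe population drops the GO success rate from
0.89 to 0.54 across the three CNO-on days (n = 6 mice per group, one
averaged point per mouse), detected at three stars.

The numbered drivers under `analysis/` run the full study: simulate all
designs (`01`), extract withdrawal-variant component peaks (`02`), build
the significance matrix (`03`), and check calibration/power (`04`). Each
writes its tables under `results/`.

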