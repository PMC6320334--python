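# seegamma

Task-specific gamma-band response analysis for intracerebral (sEEG)
recordings.

Depth-electrode recordings from epilepsy patients give millisecond-scale
access to local population activity via gamma-band (50–150 Hz) power.
When subjects perform two different discrimination tasks on the same
stimulus sequence — here judging either the *actor* or the *action* in a
video preceded by a variable-duration static frame — individual recording
leads can respond only in one task, only during one stimulus epoch, or
both.  `seegamma` implements the full analysis chain for this paradigm,
for researchers analyzing task-based sEEG data or building calibrated
simulations of it:

* **signal**: band-pass/notch filtering, 7-cycle complex Morlet
  decomposition of ten adjacent 10-Hz gamma sub-bands, 10/25-ms binning,
  per-trial z-scoring against the 1-s baseline, automated artifact
  (interictal discharge) screening;
* **classification**: per-lead two-way task × epoch ANOVA with pooled
  Benjamini–Hochberg FDR, then Tukey-HSD rules over five epoch cells
  assigning *doubly-*, *task-* or *static-specific* classes, plus
  specificity indices R = (A₁ − A₂)/(A₁ + A₂);
* **timing**: onset latency and response duration from the intersections
  of the trial-averaged trace with the 3 × baseline-SD level (10-ms bins,
  interpolated crossings), and a Bonferroni-corrected per-bin one-tailed
  inhibition test;
* **behavior**: accuracy/RT summaries, task × static-duration ANOVA and
  regression, MAD-based outlier screening, 84% psychometric threshold
  (cumulative Gaussian, 0.5 guess rate);
* **brain–behavior**: subject-level latency–RT Pearson correlation, and
  trial-wise correlation between RT and mean gamma in each lead's own
  latency-to-offset window, with an interhemispheric *push-pull* contrast
  (two-sample t-test on per-lead r by hemisphere);
* **topography**: geodesic disks on a triangulated cortical mesh with
  logistic node weights w(d) = 1/(1 + e^{2(d − 7.5 mm)}), sampling-density
  and relative-responsiveness surface maps;
* **synthetic**: a cohort generator with recorded ground truth — trial
  tables (2⁶ stimulus factorial, five static durations), RT models,
  class-conditional gamma traces with injectable latency, duration,
  amplitude and RT-coupling parameters, toy meshes — driving
  parameter-recovery tests for the whole chain.

## Worked example

```python
import numpy as np
import seegamma as sg

# simulate a 6-subject cohort at the study-condition defaults
cohort = sg.make_cohort(n_subjects=6, seed=7)

# classify every lead (screen by FDR, then Tukey rules)
trials_by_lead = {l.lead_id: cohort.trials[l.subject] for l in cohort.leads}
records = sg.classify_cohort(cohort.timecourses, trials_by_lead)
table = sg.classification_frame(records)
print("lead classes:", table["class"].value_counts().to_dict())

# response timing of one doubly-specific (ATL) lead at 10-ms bins
lead = next(l for l in cohort.leads if l.true_class == "doubly")
actor = [t for t in cohort.trials[lead.subject]
         if t.task == "actor" and t.length == "long"]
tc10 = sg.generate_lead_timecourses(
    "doubly", actor, cohort.truth, bin_ms=10.0, seed=3,
    subject_onset=cohort.subject_onsets[lead.subject])
timing = sg.estimate_latency_duration(
    tc10.average([t.trial_id for t in actor if t.correct]))
print(f"latency {timing.latency_ms:.0f} ms, duration {timing.duration_ms:.0f} ms "
      f"(threshold {timing.threshold_level:.2f} z)")

# trial-wise gamma-RT coupling in the lead's adjusted window
corr = sg.trialwise_power_rt_correlation(
    tc10, timing, cohort.trials[lead.subject], hemisphere=lead.hemisphere)
print(f"trial-wise r = {corr.r:+.2f} over {corr.n_trials} trials, "
      f"window {corr.window_ms[0]:.0f}-{corr.window_ms[1]:.0f} ms")

# relative-responsiveness map of doubly-specific leads
cls = {r.lead_id: (r.lead_class, r.overall_responsive) for r in records}
m = sg.relative_responsiveness(cohort.mesh, cohort.leads, cls, "doubly")
atl = np.concatenate([l.node_ids for l in cohort.leads if l.region == "ATL-R"])
print(f"ATL disk relative responsiveness: {np.nanmean(m.values[atl]):.0f}%")
```

Output:

```
lead classes: {'doubly': 12, 'none': 12, 'task': 6}
latency 179 ms, duration 184 ms (threshold 0.33 z)
trial-wise r = -0.11 over 64 trials, window 179-362 ms
ATL disk relative responsiveness: 100%
```

The cohort's 12 anterior-temporal leads are all recovered as
doubly-specific (responsive only to the static frame, and only in the
actor task) and the 6 occipito-temporal leads as task-specific.  The 6
fusiform leads simulated with *exactly* task-symmetric static responses
are reported unresponsive: a lead with no task effect and no task × epoch
interaction is invisible to the task-based screen (real static-specific
leads pass it through residual task modulation; see `docs/methods.md`).
The example lead's response starts 179 ms after static onset and, for
this synthetic subject, lasts 184 ms at the 3-SD level (0.33 z, from a
64-trial average).  Its single-lead trial-wise gamma–RT correlation
(−0.11) is one draw from the right-hemisphere coupling distribution
centred on −0.06; single-lead r values scatter with SD ≈ 0.13 at 64
trials, which is why hemisphere-level claims rest on hundreds of leads.
Every node of the ATL disk reports 100% relative responsiveness because
all responsive leads there are doubly-specific.

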