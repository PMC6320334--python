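# Methods

`seegamma` re-implements, as a tested library, the analysis chain used to
characterize task-specific gamma-band responses in intracerebral (sEEG)
recordings during a two-task (actor vs. action discrimination) paradigm,
together with a synthetic-cohort generator that emulates the statistical
structure the chain assumes.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not show about real recordings.

## Trial design and behavior model

A session comprises alternating action/actor discrimination blocks
(An-Ar-An-Ar), each holding one long and one short sub-block of 32 trials.
Every trial starts with a 1-s baseline, a static first frame shown for one
of five durations (275, 450, 575, 725, 875 ms), then a 1.166-s video (long
trials) or a video truncated near the subject's 84% action-discrimination
threshold (short trials, threshold +/- 100 ms).  Six binary stimulus
factors (actor, action, hand shape, hand position, size, inversion) span
2^6 = 64 distinct videos; each 32-trial sub-block enumerates the 32
non-inversion combinations once, and inversion switches between the first
and second half of the blocks.

**RT anchor.** Reaction times are measured from static-frame onset.  The
actor-task grand mean (857 ms) exceeds every static duration, and the
duration dependence of RTs is only interpretable with this anchor; the
trial-table schema documents it.

Reaction times follow

    RT = a_task + b_task * static_duration + u_subject + e,

with actor-task defaults a chosen so the grand mean is 857 ms at the
design-mean duration (580 ms) and b_actor = 0.14 ms/ms.  The action task
is not summarized numerically in the reference material beyond being
slower and more duration-dependent; defaults (grand mean 1299 ms, slope
0.55 ms/ms) reproduce that pattern and the order of magnitude of the
published F statistics.  Residual SD is 150 ms.  The subject effect
decomposes as

    u_subject = lambda * (L_subject - 179 ms) + eta,

where `L_subject` is the subject's neural onset latency (below),
lambda = 3 ms RT per ms latency, and the SD of `eta` is derived so that
the population correlation between subject mean latency and subject mean
RT equals the target 0.75 once the sampling noise of a subject mean over
~64 trials is discounted.  Accuracy is Bernoulli per condition (0.97 for
long trials and short actor trials; 0.82 for short action trials, i.e.
near the 84% threshold governing the truncation), independent of RT; all
analyses use correct trials only by default.

## Gamma-power traces

The generator emits binned z-scored gamma power directly (simulating raw
broadband voltage is a non-goal; the wavelet stage is exercised on
separately synthesized sinusoidal voltage fixtures).  Per lead class the
noiseless mean is:

* **doubly-specific** — a transient bump in the actor task only
  (onset ~179 +/- 21 ms across subjects, 3 ms within-subject jitter;
  duration ~104 +/- 38 ms across subjects); in the action task a
  suppression below baseline from 100 ms after static onset until the
  response.
* **static-specific** — the same bump in both tasks.
* **task-specific** — a sustained plateau from onset until the response,
  actor task only.
* **none** — noise only.

**Shape.** Responses are tapered-cosine (Tukey) bumps: a plateau with
raised-cosine rise/fall edges.  A pure raised cosine was rejected because
its 3-SD crossing-to-crossing interval is systematically much shorter
than its nominal width, which would divorce the duration parameter from
the quantity the timing analysis measures.  The onset/duration parameters
are *defined* as threshold-crossing quantities (that is how the reference
summary statistics were obtained); the 20-ms edge time is chosen so that
the noiseless 3-SD crossing interval of a 64-trial average reproduces the
nominal parameters at 10-ms bins to within ~2 ms.  Shapes are averaged
within bins (binned power is a within-bin mean), not sampled at bin
centers — center sampling aliases the edges and biases crossing latencies
by about minus one bin.

**Noise.** Each trial carries unit-SD white noise per bin plus a slow
component: piecewise-constant over 250-ms segments with SD 0.8.  The slow
component matters: with white noise alone, trial-level epoch means are
implausibly precise, and any visible action-task suppression would be
Tukey-significant against baseline — making the doubly-specific
definition (video epochs *not* significantly different from baseline)
unattainable.  Real gamma power fluctuates with comparable
autocorrelation.  The default suppression depth (0.15 z before
normalization) is set so that the per-lead Tukey comparison treats the
suppressed video epoch as statistically indistinguishable from baseline
while the across-subject one-tailed inhibition test can still detect
suppression on stronger fixtures.

**Normalization.** Every trial is z-scored against its own 1-s baseline,
exactly as the pipeline normalizes real data.  Consequences: baseline
bins have sample mean 0 and SD 1 *exactly* per trial (the generator's
baseline invariant holds by construction), and the baseline epoch mean is
exactly 0 in every trial, so the baseline cell of the five-cell Tukey
comparison is degenerate at zero — a property the real pipeline's
normalization implies as well.  When both noise SDs are set to zero the
normalization is skipped (flagged), giving noiseless traces for exact
shape tests.

**Trial-wise RT coupling.** For doubly-specific leads in the actor task,
a per-trial amplitude perturbation proportional to the trial's
standardized RT is added after normalization.  The coupling parameter is
the *target Pearson correlation* between the response-window mean and RT
(left +0.13, right -0.06); the generator converts it to an additive
coefficient using the realized spread of window means across trials, so
the injected population correlation in the true window equals the target
exactly.  The analysis, which re-estimates the window from the noisy
average, recovers slightly attenuated values (~0.12 / ~-0.05 at the
defaults) — honest estimator attenuation, not a calibration error.

## Signal processing (voltage path)

Voltage fixtures at 1 kHz pass a zero-phase 0.08–300 Hz band-pass
(separate 2nd-order high-pass and 4th-order low-pass Butterworth stages;
a one-shot band-pass with a 0.08-Hz edge is numerically fragile) and a
50-Hz notch (Q = 35, >= 30 dB).  The near-DC pole settles over ~2 s, so
filtered epochs should be analysed in their interior; tests use 40-s
fixtures.  Gamma power is the squared magnitude of a 7-cycle complex
Morlet transform at the centers of ten adjacent 10-Hz bands (55 ... 145
Hz), averaged across bands and within non-overlapping 10- or 25-ms bins
(bins are half-open, anchored at trial start; 7 cycles gives ~11 ms
temporal SD at 100 Hz, compatible with 10-ms bins).  Bins within half a
wavelet support of the epoch edges are flagged.  Artifact screening
flags any trial whose z trace exceeds 6 during stimulus presentation — an
automated stand-in for visual inspection of interictal discharges,
validated against the generator's injected ground truth (recall >= 0.9 at
the default threshold).

An EDF reader is deliberately out of scope; `VoltageEpoch` is a plain
array container, so any reader (e.g. `mne.io.read_raw_edf`) can feed the
chain.

## Lead classification

Trial-level epoch means (baseline [-1000, 0), static [75, 275), video
[static end, RT)) enter a two-way task x epoch ANOVA per lead; the
pooled family of (2 x n_leads) p-values (task and interaction effects)
is corrected by Benjamini-Hochberg at q = 0.05 — the conservative
single-family reading.  Trials answered before the static phase ended
have no video epoch and are excluded (logged).  Responsive leads are
classified by Tukey HSD over five cells: baseline pooled across tasks
(it cannot differ between tasks under per-trial z-scoring), static and
video epochs per task.  One-sided claims are evaluated as
Tukey-significant differences with the required sign; "not different
from baseline" is the absence of Tukey significance (accepting the null
— the operationalization the definitions imply).  Because the three
class definitions are not mutually exclusive on noisy data, rules are
evaluated in stringency order doubly -> task -> static, and a lead
matching more than one rule is flagged.  Specificity magnitudes use
R = (A1 - A2)/(A1 + A2) with negative A2 clamped to zero (flagged); the
indices are meaningful for responsive leads (A1 >= 0), where the clamped
index lies in [0, 1].

## Response timing

The threshold is 3 x the SD of the baseline bins of the *averaged* trace
(10-ms bins); latency is the first upward crossing after static onset,
duration the interval to the next downward crossing, both linearly
interpolated between adjacent bin centers (sub-bin reproducible on
noiseless fixtures).  A crossing must be sustained for `min_run_bins`
consecutive bins; the default is 3 (30 ms).  With a single-bin criterion,
~6% of 64-trial averages at the default noise show a chance supra-3SD
bin before the true onset (mean latency error -9 ms, SD 25 ms, heavy
left tail), which measurably attenuates the latency-RT correlation; at
min_run = 3 the error is -0.1 +/- 2 ms with no valid estimates lost.
Missing downward crossings censor the duration at trace end (flagged).
Estimates are produced pooled and per static duration; when onset varies
with static duration, pooling smears the average and lengthens the
pooled duration relative to the per-duration estimates — a property the
tests assert.  The inhibition test applies per-25-ms-bin one-tailed
t-tests (mean < 0) across subjects with Bonferroni correction over
window/bin comparisons (40 for 1 s, 70 for 1.75 s).

## Behavior statistics

RT ANOVAs (task x five static durations, long and short trials
independently) run on correct trials after per-subject centering
(subtracting each subject's overall mean, re-referenced to the grand
mean), which removes between-subject variance while preserving
within-subject effects; raw means are reported alongside.  The design is
balanced by construction; Type II sums of squares are used (equivalent
under balance, reasonable under mild imbalance).  The RT-outlier screen
replaces an informal by-eye criterion with a one-sided 3 x MAD rule
(normal-consistent scaling) on actor-task subject means.  The 84%
action-discrimination threshold is estimated by binomial maximum
likelihood of a cumulative-Gaussian psychometric function with guess
rate 0.5 (2AFC), p(t) = 0.5 + 0.5 Phi((t - mu)/sigma); the 84% point
(mu + 0.468 sigma) is clipped to the tested range [150, 350] ms with a
warning when the data provide no interior crossing.

## Cortical maps

Geodesic distances are edge-graph shortest paths (Dijkstra on the
triangulation's weighted edge graph) — adequate at ~1-mm edge length,
biased by less than one edge length relative to exact polyhedral
geodesics.  Node weights follow the decreasing unit logistic
w(d) = 1/(1 + exp(k (d - m))) with steepness k = 2 per mm and midpoint
m = 7.5 mm (half weight at 7.5 mm; ~0.99 at 5 mm, ~0.007 at 10 mm), so
the 5-10 mm shell is the transition zone; disks truncate at 10 mm.
Sampling density counts weighted lead-equivalents (each lead owns exactly
7 surface nodes; weighted node sum / 7), and nodes below two
lead-equivalents (14 nodes) are masked.  Relative responsiveness is the
percentage of responsive lead weight in a disk carried by a given class;
weighted counting is used for both maps for consistency.  The synthetic
mesh is a flat triangulated strip with 1-mm edges and region patches
separated by 25-mm gaps (disks can never straddle regions); it makes no
attempt to mimic cortical folding.

## Brain-behavior correlations

Subject-level: per-lead crossing latencies of a subject's anterior
temporal leads (at least two) are averaged and correlated (Pearson, plus
least squares) with the subject's mean actor-task RT.  Lead-level: the
static-epoch window is re-adjusted to the lead's own latency and
duration, the per-trial mean z in [latency, latency + duration) is
correlated with RT across correct, artifact-free long actor trials
(optionally restricted to original or inverted frames).  The push-pull
contrast is a two-sample two-tailed t-test on the raw per-lead r values
by hemisphere; Fisher's z is available as an option but is off by
default, matching the convention of reporting raw mean r.

## Problem sizes and reproducibility

Recovery runs use the sizes the summaries refer to: 200 simulated
subjects for timing, 10,000 long trials for the behavior fit, 200
replicate 11-subject cohorts for the latency-RT correlation, and 200
leads per hemisphere (64 actor trials each) for the trial-wise coupling.
Every stochastic draw derives from a single integer seed; identical
seeds give bit-identical cohorts.

A consequence worth knowing: generator static-specific leads respond
*identically* in both tasks, so they carry no task main effect and no
task x epoch interaction and are therefore invisible to the
responsiveness screen — faithfully so, since the screen is defined on
task effects.  Real static-specific leads pass the screen through
residual task modulation.  Classification recovery is therefore asserted
on `classify_lead` given responsiveness; the full pipeline will report
exactly symmetric static leads as unresponsive.

## Limitations

The generator's Gaussian white + piecewise-constant noise, fixed
response shapes, and flat mesh are idealizations: passing recovery tests
demonstrates that the analysis chain measures what it claims on data
satisfying its assumptions, not that real recordings satisfy them.
Baseline epoch means are exactly zero under per-trial z-scoring, making
baseline comparisons noiseless in a way real pipelines only approximate.
Electrode localization, template warping, eye movements, and rendering
are out of scope.
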