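"""Synthetic-cohort generator with recorded ground truth.

Emulates the statistical structure the analysis assumes: a 2 (task) x 2
(length) trial design with five static-frame durations and a 2^6 stimulus
factorial; reaction times with task- and duration-dependent means; per-lead
binned gamma-power traces with class-dependent transient / sustained /
suppressed shapes; and a toy triangulated cortical patch with leads mapped
to surface nodes.

The generator's defaults encode the study conditions (onset 179 +/- 21 ms,
duration 104 +/- 38 ms, actor RT 857 ms with slope 0.14 ms/ms, subject-level
latency-RT correlation 0.75, trial-wise gamma-RT coupling +0.13 left /
-0.06 right).  Every stochastic draw is reproducible from the seed, and the
injected parameters are recorded on the generated objects for recovery
tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .types import (
    BASELINE_WINDOW_MS,
    LONG_VIDEO_MS,
    NODES_PER_LEAD,
    STATIC_DURATIONS_MS,
    STIMULUS_FACTORS,
    GammaTimeCourse,
    LeadRecord,
    LeadTimeCourses,
    ToyMesh,
    TrialRecord,
)

#: mean of the five static durations; RT grand means are referenced to it
DESIGN_MEAN_STATIC_MS: float = float(np.mean(STATIC_DURATIONS_MS))

_REGION_ORDER = ("ATL-L", "ATL-R", "FG", "OTC", "OFC", "other")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """All injectable generator parameters, with study-condition defaults.

    Response shape parameters are in pre-normalization units; traces are
    z-scored against their own baseline before being returned, exactly as
    the analysis pipeline normalizes real data.
    """

    # response onset (ms after static onset) and duration
    onset_mean_ms: float = 179.0
    onset_sd_ms: float = 21.0            # across subjects
    onset_jitter_sd_ms: float = 3.0      # within subject, across trials
    duration_mean_ms: float = 104.0
    duration_sd_ms: float = 38.0         # across subjects
    duration_jitter_sd_ms: float = 5.0   # within subject
    min_duration_ms: float = 30.0

    # response shape
    response_amplitude: float = 5.0
    amplitude_jitter_sd: float = 0.5     # per trial, additive
    edge_taper_ms: float = 20.0          # raised-cosine rise/fall time
    suppression_depth: float = 0.15      # doubly leads, action task
    suppression_onset_ms: float = 100.0

    # noise: white per-bin component plus slow piecewise-constant component
    white_noise_sd: float = 1.0
    slow_noise_sd: float = 0.8
    slow_segment_ms: float = 250.0

    # reaction-time model: rt = intercept(task) + slope(task)*static_duration
    #                           + subject effect + residual
    rt_grand_mean_ms: dict = field(
        default_factory=lambda: {"actor": 857.0, "action": 1299.0})
    rt_slope: dict = field(default_factory=lambda: {"actor": 0.14,
                                                    "action": 0.55})
    rt_resid_sd_ms: float = 150.0
    rt_min_ms: float = 200.0

    # brain-behavior couplings
    latency_rt_slope: float = 3.0        # ms RT per ms of onset latency
    latency_rt_corr: float = 0.75        # target subject-level Pearson r
    gamma_rt_coupling: dict = field(
        default_factory=lambda: {"left": 0.13, "right": -0.06})

    # accuracy per condition
    accuracy: dict = field(default_factory=lambda: {
        ("long", "actor"): 0.97, ("long", "action"): 0.97,
        ("short", "actor"): 0.97, ("short", "action"): 0.82,
    })

    seed: int = 0

    # -- derived quantities ---------------------------------------------------

    def rt_intercept(self, task: str) -> float:
        return self.rt_grand_mean_ms[task] - self.rt_slope[task] * DESIGN_MEAN_STATIC_MS

    def subject_rt_sd(self, n_actor_trials: int = 64) -> float:
        """SD of the latency-independent part of the subject RT effect.

        Derived so that subject mean RT correlates with onset latency at
        ``latency_rt_corr`` once the sampling noise of a subject mean over
        ``n_actor_trials`` trials is accounted for.
        """
        rho = self.latency_rt_corr
        lam = self.latency_rt_slope
        if rho <= 0 or lam == 0:
            return 50.0
        total = (lam * self.onset_sd_ms) ** 2 * (1.0 / rho ** 2 - 1.0)
        total -= self.rt_resid_sd_ms ** 2 / max(n_actor_trials, 1)
        return math.sqrt(max(total, 0.0))


# ---------------------------------------------------------------------------
# trial design
# ---------------------------------------------------------------------------

def generate_trial_table(n_blocks: int = 4, short_threshold_ms: float = 225.0,
                         seed: int = 0, subject: str = "s01") -> list[TrialRecord]:
    """Enumerate the blocked 2AFC trial design.

    Blocks alternate action / actor discrimination (An-Ar-An-Ar...); each
    block holds one long and one short sub-block of 32 trials.  Each
    sub-block enumerates all 32 combinations of the five non-inversion
    stimulus factors once; the first half of the blocks uses original
    frames, the second half inverted ones, so the full design spans the
    2^6 = 64 distinct videos.  Static durations are drawn uniformly from
    the five values; short videos are truncated at the subject's 84%
    action-discrimination threshold or 100 ms earlier/later.
    """
    if n_blocks <= 0:
        raise ValueError("n_blocks must be positive")
    if not (200.0 <= short_threshold_ms <= 250.0):
        raise ValueError("short_threshold_ms must lie in [200, 250]")
    rng = np.random.default_rng(seed)
    base_factors = STIMULUS_FACTORS[:-1]          # all but inversion
    combos = np.array(
        np.meshgrid(*([[False, True]] * len(base_factors)), indexing="ij")
    ).reshape(len(base_factors), -1).T            # (32, 5)

    trials: list[TrialRecord] = []
    tid = 0
    for block in range(n_blocks):
        task = "action" if block % 2 == 0 else "actor"
        inverted = block >= n_blocks // 2
        lengths = ["long", "short"]
        rng.shuffle(lengths)
        for length in lengths:
            order = rng.permutation(len(combos))
            for k in order:
                factors = dict(zip(base_factors, map(bool, combos[k])))
                factors["inversion"] = inverted
                static = int(rng.choice(STATIC_DURATIONS_MS))
                if length == "long":
                    video, trunc = float(LONG_VIDEO_MS), None
                else:
                    trunc = short_threshold_ms + float(rng.choice([-100.0, 0.0, 100.0]))
                    video = trunc
                trials.append(TrialRecord(
                    trial_id=tid, subject=subject, task=task, length=length,
                    block=block, static_duration=static, video_duration=video,
                    truncation_offset=trunc, factors=factors,
                ))
                tid += 1
    return trials


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def generate_behavior(trials: list[TrialRecord], truth: GroundTruth,
                      seed: int = 0,
                      subject_onsets: dict[str, float] | None = None,
                      subject_effects: dict[str, float] | None = None,
                      ) -> list[TrialRecord]:
    """Fill ``rt`` and ``correct`` according to the RT model.

    RT = task intercept + task slope x static duration + subject effect +
    residual noise.  The subject effect couples to the subject's response
    onset latency (``latency_rt_slope``) plus an independent component whose
    SD is derived from the target latency-RT correlation; explicit
    ``subject_effects`` override the model (use 0 for a fixed-effect-free
    dataset).
    """
    for task in ("actor", "action"):
        if task not in truth.rt_grand_mean_ms or task not in truth.rt_slope:
            raise ValueError(f"missing RT coefficients for task {task!r}")
    rng = np.random.default_rng(seed)
    subjects = sorted({t.subject for t in trials})
    n_actor = {
        s: sum(1 for t in trials
               if t.subject == s and t.task == "actor" and t.length == "long")
        for s in subjects
    }
    effects: dict[str, float] = {}
    for s in subjects:
        if subject_effects is not None and s in subject_effects:
            effects[s] = subject_effects[s]
            continue
        onset = (subject_onsets or {}).get(s)
        if onset is None:
            onset = rng.normal(truth.onset_mean_ms, truth.onset_sd_ms)
        eta_sd = truth.subject_rt_sd(max(n_actor[s], 1))
        effects[s] = (truth.latency_rt_slope * (onset - truth.onset_mean_ms)
                      + rng.normal(0.0, eta_sd))

    out = []
    for t in trials:
        mu = (truth.rt_intercept(t.task)
              + truth.rt_slope[t.task] * t.static_duration + effects[t.subject])
        rt = max(mu + rng.normal(0.0, truth.rt_resid_sd_ms), truth.rt_min_ms)
        acc = truth.accuracy[(t.length, t.task)]
        out.append(replace(t, rt=float(rt), correct=bool(rng.random() < acc)))
    return out


# ---------------------------------------------------------------------------
# gamma-power time courses
# ---------------------------------------------------------------------------

def _tapered_bump(centers: np.ndarray, onset: float, duration: float,
                  taper: float) -> np.ndarray:
    """Unit-amplitude plateau on [onset, onset+duration] with raised-cosine
    edges of length ``taper`` (a Tukey window evaluated at the bin centers)."""
    if duration <= 0:
        return np.zeros_like(centers)
    taper = min(taper, duration / 2.0)
    t = centers - onset
    out = np.zeros_like(centers)
    inside = (t >= 0) & (t <= duration)
    tt = t[inside]
    w = np.ones_like(tt)
    if taper > 0:
        rise = tt < taper
        fall = tt > duration - taper
        w[rise] = 0.5 * (1.0 - np.cos(np.pi * tt[rise] / taper))
        w[fall] = 0.5 * (1.0 - np.cos(np.pi * (duration - tt[fall]) / taper))
    out[inside] = w
    return out


def _binned_bump(t0: float, n_bins: int, bin_ms: float, onset: float,
                 duration: float, taper: float, upsample: int = 10,
                 ) -> np.ndarray:
    """Tapered bump averaged within each bin (binned power is a within-bin
    mean, so shapes are integrated rather than sampled at bin centers)."""
    fine = t0 + (np.arange(n_bins * upsample) + 0.5) * (bin_ms / upsample)
    return _tapered_bump(fine, onset, duration, taper).reshape(
        n_bins, upsample).mean(axis=1)


def _crossing_offset_ms(taper_ms: float, rel_threshold: float) -> float:
    """Time after shape onset at which the raised-cosine edge reaches
    ``rel_threshold`` (threshold / amplitude)."""
    r = float(np.clip(rel_threshold, 0.0, 1.0))
    return taper_ms / np.pi * math.acos(1.0 - 2.0 * r)


def generate_lead_timecourses(
    lead_class: str,
    trials: list[TrialRecord],
    truth: GroundTruth,
    bin_ms: float = 25.0,
    seed: int | np.random.Generator = 0,
    *,
    hemisphere: str = "right",
    subject_onset: float | None = None,
    subject_duration: float | None = None,
    t_max_ms: float | None = None,
    lead_id: str = "lead",
    couple_rt: bool = True,
) -> LeadTimeCourses:
    """Generate per-trial z-scored gamma traces for one lead.

    Response shape by class (actor / action task):

    * ``doubly`` -- transient bump in the actor task only; in the action task
      a suppression below baseline from ``suppression_onset_ms`` after static
      onset until the response.
    * ``static`` -- the same transient bump in both tasks.
    * ``task`` -- sustained plateau from onset until the response, actor task
      only.
    * ``none`` -- noise only.

    Traces are white + slow noise plus the noiseless shape, then z-scored
    per trial against the trial's own 1-s baseline (skipped, and flagged,
    when both noise SDs are zero).  For doubly leads in the actor task a
    trial-wise amplitude perturbation is injected so that the mean z in the
    response window correlates with RT at ``gamma_rt_coupling[hemisphere]``.
    """
    if lead_class not in ("doubly", "static", "task", "none"):
        raise ValueError(f"unknown lead class {lead_class!r}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if any(t.rt is None for t in trials):
        raise ValueError("trials must have reaction times; run generate_behavior")

    if subject_onset is None:
        subject_onset = rng.normal(truth.onset_mean_ms, truth.onset_sd_ms)
    if subject_duration is None:
        subject_duration = max(
            rng.normal(truth.duration_mean_ms, truth.duration_sd_ms),
            truth.min_duration_ms)

    t0 = BASELINE_WINDOW_MS[0]
    if t_max_ms is None:
        t_max_ms = max(t.rt for t in trials) + 1000.0
    n_bins = int(math.ceil((t_max_ms - t0) / bin_ms))
    centers = t0 + (np.arange(n_bins) + 0.5) * bin_ms
    n_trials = len(trials)

    onsets = subject_onset + rng.normal(0.0, truth.onset_jitter_sd_ms, n_trials)
    durations = np.maximum(
        subject_duration + rng.normal(0.0, truth.duration_jitter_sd_ms, n_trials),
        truth.min_duration_ms / 2.0)
    amps = truth.response_amplitude + rng.normal(
        0.0, truth.amplitude_jitter_sd, n_trials)

    signal = np.zeros((n_trials, n_bins))
    truncated = np.zeros(n_trials, dtype=bool)
    for i, tr in enumerate(trials):
        if onsets[i] + durations[i] > t_max_ms:
            truncated[i] = True
        if lead_class in ("doubly", "static") and (
                lead_class == "static" or tr.task == "actor"):
            signal[i] = amps[i] * _binned_bump(
                t0, n_bins, bin_ms, onsets[i], durations[i],
                truth.edge_taper_ms)
        if lead_class == "doubly" and tr.task == "action":
            signal[i] = -truth.suppression_depth * _binned_bump(
                t0, n_bins, bin_ms, truth.suppression_onset_ms,
                tr.rt - truth.suppression_onset_ms, truth.edge_taper_ms)
        elif lead_class == "task" and tr.task == "actor":
            signal[i] = amps[i] * _binned_bump(
                t0, n_bins, bin_ms, onsets[i], tr.rt - onsets[i],
                truth.edge_taper_ms)
            if tr.rt > t_max_ms:
                truncated[i] = True

    noiseless = truth.white_noise_sd == 0 and truth.slow_noise_sd == 0
    x = signal.copy()
    if truth.white_noise_sd > 0:
        x += rng.normal(0.0, truth.white_noise_sd, size=x.shape)
    if truth.slow_noise_sd > 0:
        seg_bins = max(int(round(truth.slow_segment_ms / bin_ms)), 1)
        n_seg = int(math.ceil(n_bins / seg_bins))
        seg = rng.normal(0.0, truth.slow_noise_sd, size=(n_trials, n_seg))
        x += np.repeat(seg, seg_bins, axis=1)[:, :n_bins]

    base = (centers >= BASELINE_WINDOW_MS[0]) & (centers < BASELINE_WINDOW_MS[1])
    if not noiseless:
        mu = x[:, base].mean(axis=1, keepdims=True)
        sd = x[:, base].std(axis=1, ddof=1, keepdims=True)
        z = (x - mu) / sd
    else:
        z = x

    coupling_coef = 0.0
    rho = truth.gamma_rt_coupling.get(hemisphere, 0.0)
    actor_idx = np.array([i for i, tr in enumerate(trials) if tr.task == "actor"])
    if (couple_rt and lead_class == "doubly" and rho != 0.0
            and len(actor_idx) >= 3 and not noiseless):
        rts = np.array([trials[i].rt for i in actor_idx])
        u = (rts - rts.mean()) / rts.std(ddof=1)
        # calibrate over the full bump support: with the estimator's
        # near-unbiased crossings this matches the analysis window
        a, b = subject_onset, subject_onset + subject_duration
        grid = np.linspace(a, b, 201)
        wbar = float(_tapered_bump(grid, subject_onset, subject_duration,
                                   truth.edge_taper_ms).mean())
        win = (centers >= a) & (centers < b)
        if win.any() and wbar > 0:
            m = z[actor_idx][:, win].mean(axis=1)
            s = m.std(ddof=1)
            coupling_coef = s * abs(rho) / math.sqrt(1.0 - rho ** 2) / wbar
            coupling_coef *= math.copysign(1.0, rho)
            for j, i in enumerate(actor_idx):
                shape = _binned_bump(t0, n_bins, bin_ms, onsets[i],
                                     durations[i], truth.edge_taper_ms)
                z[i] += coupling_coef * u[j] * shape

    return LeadTimeCourses(
        values=z, bin_ms=bin_ms, t0_offset_ms=t0, lead_id=lead_id,
        trial_ids=np.array([t.trial_id for t in trials]),
        flags={"normalized": not noiseless,
               "truncated_trials": truncated},
        truth={"lead_class": lead_class, "hemisphere": hemisphere,
               "subject_onset_ms": float(subject_onset),
               "subject_duration_ms": float(subject_duration),
               "trial_onsets_ms": onsets, "trial_durations_ms": durations,
               "coupling_rho": float(rho) if lead_class == "doubly" else 0.0,
               "coupling_coef": float(coupling_coef)},
    )


def generate_timecourse(lead_class: str, trial: TrialRecord,
                        truth: GroundTruth, bin_ms: float = 25.0,
                        seed: int | np.random.Generator = 0,
                        **kwargs) -> GammaTimeCourse:
    """Single-trial convenience wrapper around generate_lead_timecourses."""
    tcs = generate_lead_timecourses(lead_class, [trial], truth, bin_ms, seed,
                                    couple_rt=False, **kwargs)
    g = tcs.get_trial(trial.trial_id)
    g.flags.update(tcs.flags)
    g.flags["truth"] = tcs.truth
    return g


# ---------------------------------------------------------------------------
# IED artifacts
# ---------------------------------------------------------------------------

def inject_ied_artifacts(tcs: LeadTimeCourses, trials: list[TrialRecord],
                         rate: float, seed: int = 0,
                         ) -> tuple[LeadTimeCourses, set[int]]:
    """Add brief large-amplitude (> 6 z) transients to a random trial subset.

    Affected trials receive a spike of 7-10 z spanning ~30 ms at a uniform
    random latency within the stimulus presentation; the affected trial ids
    are returned and recorded as ground truth in ``flags['ied_true']``.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    by_id = {t.trial_id: t for t in trials}
    values = tcs.values.copy()
    centers = tcs.bin_centers_ms
    hit = rng.random(tcs.n_trials) < rate
    flagged: set[int] = set()
    width_bins = max(int(round(30.0 / tcs.bin_ms)), 1)
    for i in np.flatnonzero(hit):
        tr = by_id[int(tcs.trial_ids[i])]
        t_stim_end = tr.static_duration + tr.video_duration
        lat = rng.uniform(0.0, max(t_stim_end - 30.0, 1.0))
        j0 = int(np.searchsorted(centers, lat))
        values[i, j0:j0 + width_bins] += rng.uniform(7.0, 10.0)
        flagged.add(int(tcs.trial_ids[i]))
    flags = dict(tcs.flags)
    flags["ied_true"] = np.isin(tcs.trial_ids, sorted(flagged))
    return (LeadTimeCourses(values=values, bin_ms=tcs.bin_ms,
                            t0_offset_ms=tcs.t0_offset_ms, lead_id=tcs.lead_id,
                            trial_ids=tcs.trial_ids, flags=flags,
                            truth=tcs.truth),
            flagged)


# ---------------------------------------------------------------------------
# mesh and leads
# ---------------------------------------------------------------------------

def generate_mesh_and_leads(n_leads_per_region: dict[str, int], seed: int = 0,
                            ) -> tuple[ToyMesh, list[LeadRecord]]:
    """Build a triangulated strip mesh (1-mm edges) with well-separated
    region patches and leads of exactly seven contiguous nodes each.

    Regions are laid out as consecutive column blocks of an 11-row grid,
    separated by 25-mm unassigned gaps so that geodesic disks (10-mm radius)
    never straddle two regions.
    """
    for r, n in n_leads_per_region.items():
        if r not in _REGION_ORDER:
            raise ValueError(f"unknown region {r!r}")
        if n < 0:
            raise ValueError("lead counts must be >= 0")
        if n > 54:
            raise ValueError(f"region {r!r} request exceeds mesh capacity (54)")
    rng = np.random.default_rng(seed)
    rows = 11
    gap_cols = 25
    lead_rows = (2, 5, 8)

    col_blocks: list[tuple[str, int, int]] = []   # (region, col0, ncols)
    col = 0
    regions = [r for r in _REGION_ORDER if n_leads_per_region.get(r, 0) > 0]
    for r in regions:
        n = n_leads_per_region[r]
        ncols = 3 * math.ceil(n / len(lead_rows)) + 3
        col_blocks.append((r, col, ncols))
        col += ncols + gap_cols
    total_cols = max(col - gap_cols if regions else 0, 0)
    total_cols = max(total_cols, math.ceil(500 / rows))   # >= 500 nodes

    def nid(i: int, j: int) -> int:
        return i * total_cols + j

    ii, jj = np.meshgrid(np.arange(rows), np.arange(total_cols), indexing="ij")
    nodes = np.column_stack([jj.ravel().astype(float), ii.ravel().astype(float),
                             np.zeros(rows * total_cols)])
    tris = []
    for i in range(rows - 1):
        for j in range(total_cols - 1):
            tris.append((nid(i, j), nid(i + 1, j), nid(i + 1, j + 1)))
            tris.append((nid(i, j), nid(i + 1, j + 1), nid(i, j + 1)))
    region_labels = np.full(rows * total_cols, "none", dtype=object)
    for r, c0, nc in col_blocks:
        for i in range(rows):
            for j in range(c0, min(c0 + nc, total_cols)):
                region_labels[nid(i, j)] = r

    leads: list[LeadRecord] = []
    for r, c0, nc in col_blocks:
        n = n_leads_per_region[r]
        hemi = "left" if r.endswith("-L") else "right"
        placed = 0
        for j in range(c0 + 1, c0 + nc - 1, 3):
            for i in lead_rows:
                if placed >= n:
                    break
                node_set = np.array([
                    nid(i, j), nid(i, j - 1), nid(i, j + 1), nid(i - 1, j),
                    nid(i + 1, j), nid(i + 1, j + 1), nid(i - 1, j - 1),
                ])
                leads.append(LeadRecord(
                    lead_id=f"{r}-{placed:02d}", hemisphere=hemi, region=r,
                    node_ids=node_set))
                placed += 1
        if placed < n:
            raise ValueError(f"region {r!r} request exceeds mesh capacity")
    return ToyMesh(nodes=nodes, triangles=np.array(tris, dtype=int),
                   node_region=region_labels), leads


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """A complete simulated data set with its ground truth."""

    subjects: list[str]
    trials: dict[str, list[TrialRecord]]       # per subject
    leads: list[LeadRecord]
    timecourses: dict[str, LeadTimeCourses]    # per lead id
    mesh: ToyMesh | None
    truth: GroundTruth
    subject_onsets: dict[str, float] = field(default_factory=dict)


_REGION_CLASS = {"ATL-L": "doubly", "ATL-R": "doubly", "FG": "static",
                 "OTC": "task", "OFC": "doubly", "other": "none"}


def make_cohort(n_subjects: int = 12, truth: GroundTruth | None = None,
                seed: int = 0, bin_ms: float = 25.0, n_blocks: int = 4,
                leads_per_subject: dict[str, int] | None = None,
                long_only_traces: bool = True,
                with_mesh: bool = True) -> SyntheticCohort:
    """Assemble subjects, trials, behavior, leads and traces into a cohort.

    Each subject receives its own blocked trial table and a set of leads
    whose response class follows its region (ATL/OFC doubly, FG static,
    OTC task, other none).  Traces are generated for long trials only by
    default (the classification and timing analyses use long trials).
    """
    truth = truth or GroundTruth(seed=seed)
    rng = np.random.default_rng(seed)
    if leads_per_subject is None:
        leads_per_subject = {"ATL-R": 2, "FG": 1, "OTC": 1, "other": 1}

    subjects = [f"s{k:02d}" for k in range(n_subjects)]
    onsets = {s: float(rng.normal(truth.onset_mean_ms, truth.onset_sd_ms))
              for s in subjects}
    durs = {s: float(max(rng.normal(truth.duration_mean_ms, truth.duration_sd_ms),
                         truth.min_duration_ms)) for s in subjects}

    region_totals = {r: n * n_subjects for r, n in leads_per_subject.items()}
    mesh, mesh_leads = (generate_mesh_and_leads(region_totals,
                                                seed=int(rng.integers(2 ** 31)))
                        if with_mesh else (None, None))

    trials: dict[str, list[TrialRecord]] = {}
    timecourses: dict[str, LeadTimeCourses] = {}
    leads: list[LeadRecord] = []
    by_region: dict[str, list[LeadRecord]] = {}
    if mesh_leads is not None:
        for lr in mesh_leads:
            by_region.setdefault(lr.region, []).append(lr)

    for s in subjects:
        tt = generate_trial_table(
            n_blocks=n_blocks,
            short_threshold_ms=float(rng.integers(200, 251)),
            seed=int(rng.integers(2 ** 31)), subject=s)
        tt = generate_behavior(tt, truth, seed=int(rng.integers(2 ** 31)),
                               subject_onsets={s: onsets[s]})
        trials[s] = tt
        subset = ([t for t in tt if t.length == "long"]
                  if long_only_traces else tt)
        t_max = max(t.rt for t in tt) + 1000.0
        for region, n in leads_per_subject.items():
            for k in range(n):
                if mesh_leads is not None:
                    lr = by_region[region].pop(0)
                else:
                    lr = LeadRecord(
                        lead_id=f"{s}-{region}-{k}", region=region,
                        hemisphere="left" if region.endswith("-L") else "right")
                lr = replace(lr, subject=s, lead_id=f"{s}-{lr.lead_id}",
                             true_class=_REGION_CLASS[region])
                tc = generate_lead_timecourses(
                    lr.true_class, subset, truth, bin_ms=bin_ms,
                    seed=rng, hemisphere=lr.hemisphere,
                    subject_onset=onsets[s], subject_duration=durs[s],
                    t_max_ms=t_max, lead_id=lr.lead_id)
                leads.append(lr)
                timecourses[lr.lead_id] = tc

    return SyntheticCohort(subjects=subjects, trials=trials, leads=leads,
                           timecourses=timecourses, mesh=mesh, truth=truth,
                           subject_onsets=onsets)


__all__ = [
    "DESIGN_MEAN_STATIC_MS", "GroundTruth", "SyntheticCohort",
    "generate_trial_table", "generate_behavior", "generate_timecourse",
    "generate_lead_timecourses", "generate_mesh_and_leads",
    "inject_ied_artifacts", "make_cohort",
]
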