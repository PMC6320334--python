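"""Parameter-recovery simulation drivers.

Each driver generates synthetic data at the recorded ground-truth
conditions, runs the corresponding analysis exactly as it would run on
real data, and returns the recovered quantity.  They are used both by the
test suite and by the acceptance script.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import summarize_behavior
from .brainbehavior import (
    hemisphere_sign_contrast,
    latency_rt_correlation,
    trialwise_power_rt_correlation,
)
from .synthetic import GroundTruth, generate_behavior, \
    generate_lead_timecourses, generate_trial_table
from .timing import estimate_latency_duration
from .types import SubjectTimingSummary, trials_to_frame


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2 ** 31, size=n)


def simulate_timing_recovery(n_subjects: int = 200,
                             truth: GroundTruth | None = None,
                             seed: int = 0, n_blocks: int = 4,
                             bin_ms: float = 10.0):
    """Recover onset latency and duration across simulated subjects.

    For each subject a doubly-specific lead is simulated over the actor
    long trials of a standard session, the correct trials averaged, and
    the 3-SD crossing latency/duration estimated.  Returns
    ``(latencies, durations)`` arrays over subjects with a valid estimate.
    """
    truth = truth or GroundTruth()
    rng = np.random.default_rng(seed)
    tt = generate_trial_table(n_blocks, 225.0, seed=int(rng.integers(2 ** 31)))
    lats, durs = [], []
    for _ in range(n_subjects):
        ttb = generate_behavior(tt, truth, seed=int(rng.integers(2 ** 31)))
        actor = [t for t in ttb if t.task == "actor" and t.length == "long"]
        tc = generate_lead_timecourses("doubly", actor, truth,
                                       bin_ms=bin_ms, seed=rng)
        avg = tc.average([t.trial_id for t in actor if t.correct])
        timing = estimate_latency_duration(avg)
        if timing.valid and not timing.censored:
            lats.append(timing.latency_ms)
            durs.append(timing.duration_ms)
    return np.array(lats), np.array(durs)


def simulate_behavior_dataset(n_trials: int = 10_000, n_subjects: int = 24,
                              truth: GroundTruth | None = None,
                              seed: int = 0):
    """Actor-task RT slope and grand mean from a large long-trial dataset.

    Generates standard sessions per subject until at least ``n_trials``
    long actor trials exist, fits the behavioral summary, and returns
    ``(slope_ms_per_ms, grand_mean_rt_ms, summary)`` for the actor task.
    """
    import pandas as pd

    truth = truth or GroundTruth()
    rng = np.random.default_rng(seed)
    per_subj = int(np.ceil(n_trials / n_subjects / 32))   # actor-long per block pair
    n_blocks = 2 * per_subj                               # half the blocks are actor
    frames = []
    for s in range(n_subjects):
        tt = generate_trial_table(n_blocks, 225.0,
                                  seed=int(rng.integers(2 ** 31)),
                                  subject=f"s{s:02d}")
        ttb = generate_behavior(tt, truth, seed=int(rng.integers(2 ** 31)))
        frames.append(trials_to_frame(ttb))
    df = pd.concat(frames, ignore_index=True)
    long_actor = df[(df.task == "actor") & (df.length == "long")]
    if len(long_actor) > n_trials:
        keep = long_actor.index[:n_trials]
        df = df[(df.task != "actor") | (df.length != "long")
                | df.index.isin(keep)]
    summary = summarize_behavior(df)
    grand_mean = float(df[(df.task == "actor") & (df.length == "long")
                          & df.correct.fillna(False)]["rt"].mean())
    return summary.slopes[("long", "actor")], grand_mean, summary


def _simulate_one_cohort(truth: GroundTruth, n_subjects: int, seed: int,
                         leads_per_subject: int = 2,
                         bin_ms: float = 10.0) -> list[SubjectTimingSummary]:
    """One cohort's subject-level ATL timing summaries."""
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_subjects):
        subj = f"s{s:02d}"
        onset = rng.normal(truth.onset_mean_ms, truth.onset_sd_ms)
        dur = max(rng.normal(truth.duration_mean_ms, truth.duration_sd_ms),
                  truth.min_duration_ms)
        tt = generate_trial_table(4, 225.0, seed=int(rng.integers(2 ** 31)),
                                  subject=subj)
        ttb = generate_behavior(tt, truth, seed=int(rng.integers(2 ** 31)),
                                subject_onsets={subj: onset})
        actor = [t for t in ttb if t.task == "actor" and t.length == "long"]
        correct_ids = [t.trial_id for t in actor if t.correct]
        lead_lats = []
        for _ in range(leads_per_subject):
            tc = generate_lead_timecourses(
                "doubly", actor, truth, bin_ms=bin_ms, seed=rng,
                subject_onset=onset, subject_duration=dur)
            timing = estimate_latency_duration(tc.average(correct_ids))
            if timing.valid:
                lead_lats.append(timing.latency_ms)
        if len(lead_lats) >= 2:
            rts = [t.rt for t in actor if t.correct]
            out.append(SubjectTimingSummary(
                subject=subj, region="ATL",
                mean_latency_ms=float(np.mean(lead_lats)),
                mean_rt_ms=float(np.mean(rts)), n_leads=len(lead_lats)))
    return out


def simulate_latency_rt(n_cohorts: int = 200, n_subjects: int = 11,
                        truth: GroundTruth | None = None, seed: int = 0):
    """Subject-level latency-RT Pearson r over replicate cohorts.

    Returns the array of per-cohort r values (mean of which recovers the
    injected latency-RT coupling).
    """
    truth = truth or GroundTruth()
    rs = []
    for s in _child_seeds(seed, n_cohorts):
        summaries = _simulate_one_cohort(truth, n_subjects, int(s))
        if len(summaries) >= 3:
            rs.append(latency_rt_correlation(summaries).r)
    return np.array(rs)


def simulate_trialwise_coupling(hemisphere: str, n_leads: int = 200,
                                truth: GroundTruth | None = None,
                                seed: int = 0, bin_ms: float = 10.0):
    """Trial-wise adjusted-window gamma-RT correlations for doubly leads.

    Each lead sees the actor long trials of a standard session (64 trials,
    >= 60 after accuracy filtering); the lead's own crossing window is
    re-estimated and the per-trial window mean correlated with RT.
    Returns the array of per-lead r values.
    """
    truth = truth or GroundTruth()
    rng = np.random.default_rng(seed)
    tt = generate_trial_table(4, 225.0, seed=int(rng.integers(2 ** 31)))
    rs = []
    while len(rs) < n_leads:
        ttb = generate_behavior(tt, truth, seed=int(rng.integers(2 ** 31)))
        actor = [t for t in ttb if t.task == "actor" and t.length == "long"]
        tc = generate_lead_timecourses("doubly", actor, truth, bin_ms=bin_ms,
                                       seed=rng, hemisphere=hemisphere)
        timing = estimate_latency_duration(
            tc.average([t.trial_id for t in actor if t.correct]))
        if not timing.valid:
            continue
        c = trialwise_power_rt_correlation(tc, timing, ttb,
                                           hemisphere=hemisphere)
        rs.append(c.r)
    return np.array(rs)


def simulate_hemisphere_contrast(n_replicates: int = 20,
                                 leads_per_hemisphere: int = 22,
                                 truth: GroundTruth | None = None,
                                 seed: int = 0, alpha: float = 0.01):
    """Push-pull power: fraction of replicate lead samples in which the
    interhemispheric sign contrast is significant at ``alpha``."""
    truth = truth or GroundTruth()
    hits = []
    for k, s in enumerate(_child_seeds(seed, n_replicates)):
        corrs = []
        for hemi in ("left", "right"):
            rs = simulate_trialwise_coupling(hemi, leads_per_hemisphere,
                                             truth, seed=int(s) + (hemi == "left"))
            from .types import LeadRTCorrelation
            corrs += [LeadRTCorrelation(lead_id=f"{hemi}{i}", hemisphere=hemi,
                                        r=float(r), p=1.0, n_trials=60,
                                        window_ms=(0.0, 1.0))
                      for i, r in enumerate(rs)]
        res = hemisphere_sign_contrast(corrs)
        hits.append(res.p < alpha)
    return float(np.mean(hits))


__all__ = [
    "simulate_behavior_dataset", "simulate_hemisphere_contrast",
    "simulate_latency_rt", "simulate_timing_recovery",
    "simulate_trialwise_coupling",
]
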