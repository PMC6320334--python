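"""Brain-behavior correlations.

Three analyses relate gamma responses to reaction times:

1. subject-level: mean response onset latency of a subject's anterior
   temporal leads against that subject's mean RT (Pearson r + regression);
2. lead-level: trial-wise correlation between the mean z in the lead's own
   latency-to-offset window and RT in actor discrimination;
3. the interhemispheric push-pull contrast: a two-sample t-test on the
   trial-wise correlation coefficients of left- versus right-hemisphere
   leads (opposite signs indicate antagonistic coupling to behavior).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import (
    GammaTimeCourse,
    LeadRTCorrelation,
    LeadTimeCourses,
    ResponseTiming,
    SubjectTimingSummary,
    TrialRecord,
)


@dataclass
class LatencyRTResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


@dataclass
class HemisphereContrast:
    t: float
    df: int
    p: float
    mean_left: float
    mean_right: float
    n_left: int
    n_right: int


def latency_rt_correlation(summaries: list[SubjectTimingSummary],
                           ) -> LatencyRTResult:
    """Pearson correlation and least-squares line between subject mean
    latency and subject mean RT."""
    if len(summaries) < 3:
        raise ValueError("need at least 3 subjects")
    lat = np.array([s.mean_latency_ms for s in summaries], dtype=float)
    rt = np.array([s.mean_rt_ms for s in summaries], dtype=float)
    if np.std(lat) == 0 or np.std(rt) == 0:
        raise ValueError("undefined correlation: zero variance")
    r, p = stats.pearsonr(lat, rt)
    reg = stats.linregress(lat, rt)
    return LatencyRTResult(r=float(r), p=float(p), slope=float(reg.slope),
                           intercept=float(reg.intercept), n=len(summaries))


def trialwise_power_rt_correlation(
    tcs: LeadTimeCourses,
    timing: ResponseTiming,
    trials: list[TrialRecord],
    *,
    hemisphere: str = "right",
    tasks: tuple[str, ...] = ("actor",),
    lengths: tuple[str, ...] = ("long",),
    frame_subset: str = "all",
    require_correct: bool = True,
    min_trials: int = 10,
) -> LeadRTCorrelation:
    """Per-trial mean z in the lead's adjusted window [latency,
    latency + duration) correlated with RT across trials.

    ``frame_subset`` restricts trials to original or inverted first frames
    (the inversion stimulus factor) when requested.
    """
    if not timing.valid:
        raise ValueError("timing estimate is not valid for this lead")
    if frame_subset not in ("all", "original", "inverted"):
        raise ValueError(f"unknown frame_subset {frame_subset!r}")
    w0 = timing.latency_ms
    w1 = timing.latency_ms + timing.duration_ms
    centers = tcs.bin_centers_ms
    win = (centers >= w0) & (centers < w1)
    if not win.any():
        raise ValueError("adjusted window contains no bins")

    present = set(map(int, tcs.trial_ids))
    keep = []
    for t in trials:
        if t.trial_id not in present or t.task not in tasks \
                or t.length not in lengths or t.ied_flag or t.rt is None:
            continue
        if require_correct and t.correct is False:
            continue
        if frame_subset == "original" and t.factors.get("inversion"):
            continue
        if frame_subset == "inverted" and not t.factors.get("inversion"):
            continue
        keep.append(t)

    flags = {}
    if len(keep) < min_trials:
        flags["low_n"] = True
    if len(keep) < 3:
        raise ValueError("fewer than 3 usable trials")
    rows = [tcs.trial_index(t.trial_id) for t in keep]
    m = tcs.values[rows][:, win].mean(axis=1)
    rt = np.array([t.rt for t in keep], dtype=float)
    r, p = stats.pearsonr(m, rt)
    return LeadRTCorrelation(lead_id=tcs.lead_id, hemisphere=hemisphere,
                             r=float(r), p=float(p), n_trials=len(keep),
                             window_ms=(float(w0), float(w1)), flags=flags)


def hemisphere_sign_contrast(correlations: list[LeadRTCorrelation],
                             *, fisher_z: bool = False) -> HemisphereContrast:
    """Two-sample two-tailed t-test on trial-wise r values by hemisphere.

    By default raw r values are compared (matching the convention of
    reporting raw mean r per hemisphere); ``fisher_z`` applies the
    variance-stabilizing transform first (the test only, means stay raw).
    """
    left = np.array([c.r for c in correlations if c.hemisphere == "left"])
    right = np.array([c.r for c in correlations if c.hemisphere == "right"])
    if len(left) < 2 or len(right) < 2:
        raise ValueError("need at least 2 leads per hemisphere")
    a, b = (np.arctanh(left), np.arctanh(right)) if fisher_z else (left, right)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0      # degenerate equal-constant groups
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return HemisphereContrast(
        t=float(t), df=len(left) + len(right) - 2, p=float(p),
        mean_left=float(left.mean()), mean_right=float(right.mean()),
        n_left=len(left), n_right=len(right))


def subject_timing_summaries(
    latencies_by_subject_lead: dict[str, dict[str, float]],
    mean_rt_by_subject: dict[str, float],
    region: str = "ATL",
    min_leads: int = 2,
) -> list[SubjectTimingSummary]:
    """Average each subject's per-lead latencies into one summary per
    subject (subjects with fewer than ``min_leads`` region leads dropped)."""
    out = []
    for subj, lat in latencies_by_subject_lead.items():
        vals = [v for v in lat.values() if np.isfinite(v)]
        if len(vals) < min_leads or subj not in mean_rt_by_subject:
            continue
        out.append(SubjectTimingSummary(
            subject=subj, region=region,
            mean_latency_ms=float(np.mean(vals)),
            mean_rt_ms=float(mean_rt_by_subject[subj]), n_leads=len(vals)))
    return out


__all__ = [
    "HemisphereContrast", "LatencyRTResult", "hemisphere_sign_contrast",
    "latency_rt_correlation", "subject_timing_summaries",
    "trialwise_power_rt_correlation",
]
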