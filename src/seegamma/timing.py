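"""Onset latency and response duration by 3-SD threshold crossing, and the
per-bin inhibition test.

Latency is the interval between static onset and the first upward crossing
of the trial-averaged z trace (10-ms bins) with the level 3 x SD of its
baseline bins; duration is the interval to the next downward crossing.
Crossing times are linearly interpolated between adjacent bin centers.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .types import (
    BASELINE_WINDOW_MS,
    GammaTimeCourse,
    LeadTimeCourses,
    ResponseTiming,
    TrialRecord,
)


def estimate_latency_duration(
    avg_trace: GammaTimeCourse,
    baseline_window: tuple[float, float] = BASELINE_WINDOW_MS,
    *,
    threshold: float | None = None,
    min_run_bins: int = 3,
    search_start_ms: float = 0.0,
) -> ResponseTiming:
    """Threshold-crossing latency/duration of an averaged trace.

    ``threshold`` defaults to 3 x the SD of the baseline bins of the
    averaged trace (the level above the zero mean); an explicit value
    overrides it.  The first upward crossing is searched from static onset
    to the end of the trace; ``min_run_bins`` consecutive supra-threshold
    bins are required to accept a crossing (default 3, i.e. 30 ms of
    sustained supra-threshold activity at 10-ms bins: brief chance
    excursions at the 3-SD level are common enough on averaged traces to
    bias onset estimates, see docs/methods.md).  A missing downward
    crossing censors the duration at trace end.
    """
    v = np.asarray(avg_trace.values, dtype=float)
    c = avg_trace.bin_centers_ms
    if threshold is None:
        base = (c >= baseline_window[0]) & (c < baseline_window[1])
        if base.sum() < 2:
            raise ValueError("baseline window contains fewer than two bins")
        threshold = 3.0 * float(v[base].std(ddof=1))
    above = v >= threshold

    def interp(i: int) -> float:
        """Crossing time between bin centers i-1 and i."""
        if v[i] == v[i - 1]:
            return float(c[i])
        f = (threshold - v[i - 1]) / (v[i] - v[i - 1])
        return float(c[i - 1] + f * avg_trace.bin_ms)

    up = None
    n = len(v)
    for i in range(1, n):
        if c[i] <= search_start_ms:
            continue
        if above[i] and not above[i - 1]:
            if above[i:i + min_run_bins].sum() >= min(min_run_bins, n - i):
                up = i
                break
    if up is None:
        return ResponseTiming(latency_ms=float("nan"),
                              duration_ms=float("nan"),
                              threshold_level=float(threshold), valid=False)
    t_up = max(interp(up), search_start_ms)

    down = None
    for j in range(up + 1, n):
        if not above[j] and above[j - 1]:
            down = j
            break
    if down is None:
        t_down = float(c[-1] + avg_trace.bin_ms / 2.0)
        censored = True
    else:
        t_down = interp(down)
        censored = False
    return ResponseTiming(
        latency_ms=t_up - search_start_ms, duration_ms=t_down - t_up,
        threshold_level=float(threshold), valid=True, censored=censored,
        flags={"duration_censored": censored} if censored else {})


def timing_by_static_duration(tcs: LeadTimeCourses,
                              trials: list[TrialRecord],
                              *, tasks: tuple[str, ...] = ("actor",),
                              require_correct: bool = True,
                              min_trials: int = 5,
                              **kwargs) -> ResponseTiming:
    """Pooled and per-static-duration timing estimates for one lead.

    Averages the lead's usable long trials (per task filter), estimates the
    pooled crossing times, then repeats the estimate for the five static
    durations independently.
    """
    by_id = {t.trial_id: t for t in trials}
    keep = [t for t in trials
            if t.length == "long" and t.task in tasks and not t.ied_flag
            and (t.correct or not require_correct)
            and t.trial_id in set(map(int, tcs.trial_ids))]
    if len(keep) < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {len(keep)}")
    pooled = estimate_latency_duration(
        tcs.average([t.trial_id for t in keep]), **kwargs)
    per: dict[int, ResponseTiming] = {}
    for dur in sorted({t.static_duration for t in keep}):
        ids = [t.trial_id for t in keep if t.static_duration == dur]
        if len(ids) >= 2:
            per[dur] = estimate_latency_duration(tcs.average(ids), **kwargs)
    pooled.per_static_duration = per
    return pooled


def inhibition_test(traces: np.ndarray, bin_ms: float, window_ms: float,
                    t0_offset_ms: float = -1000.0, alpha: float = 0.05,
                    ) -> dict:
    """Per-bin one-tailed t-test for suppression below zero.

    ``traces`` is (n_subjects, n_bins); bins with centers in
    [0, window_ms) after static onset are tested for a mean below zero
    with Bonferroni correction over window_ms / bin_ms comparisons
    (40 for a 1000-ms window at 25-ms bins, 70 for 1750 ms).
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 3:
        raise ValueError("need at least 3 traces (subjects/leads)")
    if abs(window_ms / bin_ms - round(window_ms / bin_ms)) > 1e-9:
        raise ValueError("window_ms must be divisible by bin_ms")
    factor = int(round(window_ms / bin_ms))
    centers = t0_offset_ms + (np.arange(traces.shape[1]) + 0.5) * bin_ms
    sel = (centers >= 0) & (centers < window_ms)
    sub = traces[:, sel]
    t, p = stats.ttest_1samp(sub, 0.0, axis=0, alternative="less")
    return {
        "bin_centers_ms": centers[sel], "t": t, "p": p,
        "bonferroni_factor": factor,
        "significant": p < alpha / factor,
    }


__all__ = ["estimate_latency_duration", "inhibition_test",
           "timing_by_static_duration"]
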