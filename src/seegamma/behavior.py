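"""Behavioral analyses: accuracy, RT ANOVA/regression, outlier screening
and the 84% action-discrimination threshold.

Reaction times enter a two-way task x static-duration ANOVA (long and short
trials independently, correct trials only) after per-subject centering,
plus a per-task least-squares regression of RT on static duration.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import STATIC_DURATIONS_MS, TrialRecord, trials_to_frame


@dataclass
class BehaviorSummary:
    accuracy: pd.DataFrame                 # per task x length
    anova: dict[str, pd.DataFrame]         # per length
    slopes: dict[tuple[str, str], float]   # (length, task) -> ms/ms
    intercepts: dict[tuple[str, str], float]
    rt_means: pd.DataFrame                 # raw means per task x duration x length
    flags: dict = field(default_factory=dict)


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials.copy()
    return trials_to_frame(trials)


def summarize_behavior(trials, center_by_subject: bool = True,
                       ) -> BehaviorSummary:
    """Accuracy per condition, RT ANOVA and RT-vs-duration regression.

    ANOVA and regression use correct trials; RTs are centered on each
    subject's overall mean (re-referenced to the grand mean) when more
    than one subject is present, removing between-subject variance while
    preserving the within-subject task and duration effects.  Raw
    (uncentered) means are reported alongside.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = _as_frame(trials)
    acc = (df.assign(correct=df["correct"].astype(float))
             .groupby(["task", "length"])["correct"].mean().unstack())

    rt = df[df["correct"].fillna(False) & df["rt"].notna()].copy()
    if center_by_subject and rt["subject"].nunique() > 1:
        grand = rt["rt"].mean()
        rt["rt_c"] = rt["rt"] - rt.groupby("subject")["rt"].transform("mean") + grand
    else:
        rt["rt_c"] = rt["rt"]

    anova: dict[str, pd.DataFrame] = {}
    slopes: dict[tuple[str, str], float] = {}
    intercepts: dict[tuple[str, str], float] = {}
    for length in sorted(rt["length"].unique()):
        sub = rt[rt["length"] == length]
        counts = sub.groupby(["task", "static_duration"]).size()
        for task in sorted(sub["task"].unique()):
            for dur in STATIC_DURATIONS_MS:
                if counts.get((task, dur), 0) == 0:
                    raise ValueError(
                        f"empty cell: task={task}, static_duration={dur}, "
                        f"length={length}")
        fit = ols("rt_c ~ C(task) * C(static_duration)", data=sub).fit()
        anova[length] = sm.stats.anova_lm(fit, typ=2)
        for task in sorted(sub["task"].unique()):
            s = sub[sub["task"] == task]
            res = stats.linregress(s["static_duration"], s["rt_c"])
            slopes[(length, task)] = float(res.slope)
            intercepts[(length, task)] = float(res.intercept)

    rt_means = (rt.groupby(["length", "task", "static_duration"])["rt"]
                  .mean().rename("mean_rt").reset_index())
    return BehaviorSummary(accuracy=acc, anova=anova, slopes=slopes,
                           intercepts=intercepts, rt_means=rt_means)


def flag_rt_outlier_subjects(actor_mean_rts: pd.Series | dict,
                             n_mad: float = 3.0) -> set[str]:
    """Subjects whose actor-task mean RT exceeds the cohort median by more
    than ``n_mad`` x MAD (normal-consistent scaling), one-sided.

    A reproducible stand-in for informal by-eye outlier removal.
    """
    s = pd.Series(actor_mean_rts, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 subjects")
    med = s.median()
    mad = stats.median_abs_deviation(s, scale="normal")
    if mad == 0:
        return set(s.index[s > med])
    return set(s.index[s > med + n_mad * mad])


def estimate_action_threshold(truncation_ms, correct,
                              target: float = 0.84,
                              bounds: tuple[float, float] = (150.0, 350.0),
                              min_trials_per_point: int = 10) -> float:
    """84%-correct truncation time from a cumulative-Gaussian psychometric
    fit with a 0.5 guess rate (2AFC).

    p(correct | t) = 0.5 + 0.5 * Phi((t - mu) / sigma), fitted by binomial
    maximum likelihood over the truncation points; the returned time solves
    p = ``target`` and is clipped to ``bounds`` (with a warning) when the
    data provide no crossing inside them.
    """
    t = np.asarray(truncation_ms, dtype=float)
    y = np.asarray(correct, dtype=float)
    pts = np.unique(t)
    n = np.array([(t == p).sum() for p in pts])
    k = np.array([y[t == p].sum() for p in pts])
    if (n < min_trials_per_point).any():
        warnings.warn(f"fewer than {min_trials_per_point} trials at some "
                      "truncation points", stacklevel=2)
    if np.all(k == n):
        warnings.warn("all trials correct: threshold clipped to lower bound",
                      stacklevel=2)
        return bounds[0]
    if np.all(k / n <= 0.5):
        warnings.warn("performance at chance: threshold clipped to upper "
                      "bound", stacklevel=2)
        return bounds[1]

    def nll(theta):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        p = 0.5 + 0.5 * stats.norm.cdf((pts - mu) / sigma)
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -np.sum(k * np.log(p) + (n - k) * np.log(1 - p))

    res = optimize.minimize(nll, x0=[float(np.median(pts)), np.log(100.0)],
                            method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-8})
    mu, sigma = res.x[0], float(np.exp(res.x[1]))
    z = stats.norm.ppf((target - 0.5) / 0.5)
    thr = mu + sigma * z
    if thr < bounds[0] or thr > bounds[1]:
        warnings.warn(f"threshold {thr:.0f} ms outside {bounds}; clipped",
                      stacklevel=2)
    return float(np.clip(thr, *bounds))


__all__ = ["BehaviorSummary", "estimate_action_threshold",
           "flag_rt_outlier_subjects", "summarize_behavior"]
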