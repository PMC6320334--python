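"""Overall-responsiveness screening and specificity classification of leads.

Per lead, trial-level epoch means (baseline BEp, static SEp, video VEp) feed
a two-way task x epoch ANOVA; leads whose task or interaction effect
survives Benjamini-Hochberg FDR over the pooled family are
overall-responsive.  Responsive leads are then classified by Tukey HSD
comparisons over five cells (BEp pooled across tasks, SEp and VEp per task):

* doubly-specific: SEp(actor) above both SEp(action) and baseline, with
  VEp indistinguishable from baseline in both tasks;
* task-specific: SEp and VEp in the actor task above their action-task
  counterparts and baseline;
* static-specific: SEp above baseline in both tasks, VEp indistinguishable
  from baseline in both.

Rules are evaluated in the order doubly -> task -> static (most stringent
first); a lead matching more than one rule is flagged.  Specificity
magnitudes use R = (A1 - A2) / (A1 + A2) with negative A2 clamped to zero.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    BASELINE_WINDOW_MS,
    STATIC_EPOCH_WINDOW_MS,
    LeadClassification,
    LeadTimeCourses,
    SpecificityIndices,
    TrialRecord,
)

logger = logging.getLogger(__name__)


def compute_epoch_means(tcs: LeadTimeCourses, trials: list[TrialRecord],
                        *, require_correct: bool = True,
                        exclude_ied: bool = True) -> pd.DataFrame:
    """One (BEp, SEp, VEp) triple per usable long trial of one lead.

    Trials that are short, incorrect (optional), IED-flagged (optional),
    or answered before the static phase ended (VEp undefined) are excluded
    and logged.
    """
    by_id = {t.trial_id: t for t in trials}
    centers = tcs.bin_centers_ms
    bep = (centers >= BASELINE_WINDOW_MS[0]) & (centers < BASELINE_WINDOW_MS[1])
    sep = ((centers >= STATIC_EPOCH_WINDOW_MS[0])
           & (centers < STATIC_EPOCH_WINDOW_MS[1]))
    rows = []
    for i, tid in enumerate(tcs.trial_ids):
        tr = by_id[int(tid)]
        if tr.length != "long":
            continue
        if require_correct and tr.correct is False:
            continue
        if exclude_ied and tr.ied_flag:
            continue
        if tr.rt is None:
            continue
        if tr.rt <= tr.static_end_ms:
            logger.info("lead %s trial %s: response before static end, "
                        "VEp undefined; trial excluded", tcs.lead_id, tid)
            continue
        vep = (centers >= tr.static_end_ms) & (centers < tr.rt)
        if not vep.any():
            continue
        v = tcs.values[i]
        rows.append({
            "trial_id": int(tid), "task": tr.task,
            "static_duration": tr.static_duration, "rt": tr.rt,
            "bep": float(v[bep].mean()), "sep": float(v[sep].mean()),
            "vep": float(v[vep].mean()),
        })
    return pd.DataFrame(rows)


def _anova_pvalues(em: pd.DataFrame) -> tuple[float, float]:
    """Two-way task x epoch ANOVA on trial-level epoch means."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    long = em.melt(id_vars=["trial_id", "task"],
                   value_vars=["bep", "sep", "vep"],
                   var_name="epoch", value_name="z")
    fit = ols("z ~ C(task) * C(epoch)", data=long).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    return (float(table.loc["C(task)", "PR(>F)"]),
            float(table.loc["C(task):C(epoch)", "PR(>F)"]))


def screen_overall_responsive(epoch_means: dict[str, pd.DataFrame],
                              q: float = 0.05) -> pd.DataFrame:
    """Per-lead ANOVA p-values with pooled Benjamini-Hochberg FDR at ``q``.

    The family pools both effect types (task, task x epoch) across all
    leads; a lead is overall-responsive if either of its effects survives.
    """
    from statsmodels.stats.multitest import multipletests

    rows = []
    for lead_id, em in epoch_means.items():
        if len(em) == 0 or em["task"].nunique() < 2 or \
                em.groupby("task").size().min() < 2:
            logger.info("lead %s skipped: unbalanced/empty task cell", lead_id)
            continue
        p_task, p_int = _anova_pvalues(em)
        rows.append({"lead_id": lead_id, "p_task": p_task,
                     "p_interaction": p_int})
    out = pd.DataFrame(rows)
    if len(out) == 0:
        out["responsive"] = []
        return out
    pooled = np.concatenate([out["p_task"], out["p_interaction"]])
    reject, *_ = multipletests(pooled, alpha=q, method="fdr_bh")
    n = len(out)
    out["task_rejected"] = reject[:n]
    out["interaction_rejected"] = reject[n:]
    out["responsive"] = out["task_rejected"] | out["interaction_rejected"]
    return out


_CELLS = ("bep", "sep_actor", "sep_action", "vep_actor", "vep_action")


def _tukey_cells(em: pd.DataFrame) -> dict[str, np.ndarray]:
    actor = em[em["task"] == "actor"]
    action = em[em["task"] == "action"]
    return {
        "bep": em["bep"].to_numpy(),          # baseline pooled across tasks
        "sep_actor": actor["sep"].to_numpy(),
        "sep_action": action["sep"].to_numpy(),
        "vep_actor": actor["vep"].to_numpy(),
        "vep_action": action["vep"].to_numpy(),
    }


def classify_lead(em: pd.DataFrame, alpha: float = 0.05) -> tuple[str, dict]:
    """Tukey-HSD rule classification of one overall-responsive lead.

    Returns ``(lead_class, detail)`` where detail carries the cell means,
    the Tukey p-value matrix and any flags (multi-rule match,
    unclassifiable cells).
    """
    cells = _tukey_cells(em)
    ns = {k: len(v) for k, v in cells.items()}
    if min(ns.values()) < 2:
        logger.info("unclassifiable lead: cell sizes %s", ns)
        return "none", {"flags": {"unclassifiable": True}, "cell_n": ns}
    groups = [cells[k] for k in _CELLS]
    res = stats.tukey_hsd(*groups)
    means = {k: float(v.mean()) for k, v in cells.items()}
    idx = {k: i for i, k in enumerate(_CELLS)}

    def greater(a: str, b: str) -> bool:
        """a significantly greater than b (Tukey-significant + sign)."""
        return (res.pvalue[idx[a], idx[b]] < alpha) and (means[a] > means[b])

    def differs(a: str, b: str) -> bool:
        return res.pvalue[idx[a], idx[b]] < alpha

    rule_doubly = (greater("sep_actor", "sep_action")
                   and greater("sep_actor", "bep")
                   and not differs("vep_actor", "bep")
                   and not differs("vep_action", "bep"))
    rule_task = (greater("sep_actor", "sep_action")
                 and greater("sep_actor", "bep")
                 and greater("vep_actor", "vep_action")
                 and greater("vep_actor", "bep"))
    rule_static = (greater("sep_actor", "bep")
                   and greater("sep_action", "bep")
                   and not differs("vep_actor", "bep")
                   and not differs("vep_action", "bep"))
    matches = [name for name, hit in
               (("doubly", rule_doubly), ("task", rule_task),
                ("static", rule_static)) if hit]
    lead_class = matches[0] if matches else "none"
    detail = {"cell_means": means, "tukey_pvalues": res.pvalue,
              "cell_n": ns, "flags": {}}
    if len(matches) > 1:
        detail["flags"]["multi_rule"] = matches
        logger.info("lead matched multiple rules %s; kept %s",
                    matches, lead_class)
    return lead_class, detail


def specificity_indices(em: pd.DataFrame) -> SpecificityIndices:
    """Task (R_pa) and static (R_sv) indices, R = (A1 - A2)/(A1 + A2).

    R_pa compares static-epoch responses between actor (A1) and action (A2)
    discrimination; R_sv compares static (A1) and video (A2) epochs within
    actor discrimination.  Negative A2 is clamped to zero (flagged); a zero
    A1 + A2 after clamping leaves the index undefined (NaN, flagged).
    """
    actor = em[em["task"] == "actor"]
    action = em[em["task"] == "action"]

    def index(a1: float, a2: float) -> tuple[float, bool, bool]:
        clamped = a2 < 0
        a2 = max(a2, 0.0)
        if a1 + a2 == 0:
            return float("nan"), clamped, True
        return (a1 - a2) / (a1 + a2), clamped, False

    r_pa, cl_pa, un_pa = index(float(actor["sep"].mean()),
                               float(action["sep"].mean()))
    r_sv, cl_sv, un_sv = index(float(actor["sep"].mean()),
                               float(actor["vep"].mean()))
    return SpecificityIndices(r_pa=r_pa, r_sv=r_sv, clamped_pa=cl_pa,
                              clamped_sv=cl_sv, undefined_pa=un_pa,
                              undefined_sv=un_sv)


def classify_cohort(timecourses: dict[str, LeadTimeCourses],
                    trials_by_lead: dict[str, list[TrialRecord]],
                    q: float = 0.05, alpha: float = 0.05,
                    ) -> list[LeadClassification]:
    """Screen + classify every lead; returns one record per screened lead."""
    ems = {lid: compute_epoch_means(tc, trials_by_lead[lid])
           for lid, tc in timecourses.items()}
    ems = {lid: em for lid, em in ems.items() if len(em) > 0}
    screen = screen_overall_responsive(ems, q=q)
    out: list[LeadClassification] = []
    for _, row in screen.iterrows():
        lid = row["lead_id"]
        em = ems[lid]
        rec = LeadClassification(
            lead_id=lid, overall_responsive=bool(row["responsive"]),
            p_task=float(row["p_task"]),
            p_interaction=float(row["p_interaction"]))
        if rec.overall_responsive:
            rec.lead_class, detail = classify_lead(em, alpha=alpha)
            rec.flags.update(detail.get("flags", {}))
            si = specificity_indices(em)
            rec.r_pa, rec.r_sv = si.r_pa, si.r_sv
            rec.clamped_pa, rec.clamped_sv = si.clamped_pa, si.clamped_sv
        out.append(rec)
    return out


def classification_frame(records: list[LeadClassification]) -> pd.DataFrame:
    """Per-lead classification table (exportable as CSV)."""
    return pd.DataFrame([{
        "lead_id": r.lead_id, "overall_responsive": r.overall_responsive,
        "p_task": r.p_task, "p_interaction": r.p_interaction,
        "class": r.lead_class, "r_pa": r.r_pa, "r_sv": r.r_sv,
        "clamped_pa": r.clamped_pa, "clamped_sv": r.clamped_sv,
        "flags": ";".join(sorted(r.flags)),
    } for r in records])


__all__ = [
    "classification_frame", "classify_cohort", "classify_lead",
    "compute_epoch_means", "screen_overall_responsive",
    "specificity_indices",
]
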