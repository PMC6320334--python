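"""Epoch means, responsiveness screening (FDR), Tukey-rule classification
and specificity indices."""
import numpy as np
import pandas as pd
import pytest

import seegamma as sg
from seegamma.types import LeadTimeCourses


def constant_lead(trials, value, bin_ms=25.0, t_max=2500.0):
    n_bins = int((t_max + 1000.0) / bin_ms)
    return LeadTimeCourses(
        values=np.full((len(trials), n_bins), float(value)), bin_ms=bin_ms,
        t0_offset_ms=-1000.0, lead_id="const",
        trial_ids=np.array([t.trial_id for t in trials]))


class TestEpochMeans:
    def test_constant_trace_gives_constant_means(self, long_trials):
        em = sg.compute_epoch_means(constant_lead(long_trials, 2.0),
                                    long_trials)
        assert len(em) > 0
        for col in ("bep", "sep", "vep"):
            np.testing.assert_allclose(em[col], 2.0)

    def test_baseline_only_lead_near_zero(self, truth, long_trials):
        tc = sg.generate_lead_timecourses("none", long_trials, truth, seed=1)
        em = sg.compute_epoch_means(tc, long_trials)
        # per-trial z-scoring pins BEp at exactly zero; SEp/VEp are noise
        np.testing.assert_allclose(em["bep"], 0.0, atol=1e-12)
        assert abs(em["sep"].mean()) < 0.3
        assert abs(em["vep"].mean()) < 0.3

    def test_early_response_trials_excluded(self, long_trials):
        from dataclasses import replace
        early = [replace(t, rt=min(t.rt, t.static_duration - 50.0))
                 for t in long_trials[:4]]
        rest = long_trials[4:]
        trials = early + rest
        em = sg.compute_epoch_means(constant_lead(trials, 1.0), trials)
        assert set(em.trial_id).isdisjoint({t.trial_id for t in early})

    def test_short_and_incorrect_trials_excluded(self, session_trials):
        em = sg.compute_epoch_means(constant_lead(session_trials, 1.0),
                                    session_trials)
        by_id = {t.trial_id: t for t in session_trials}
        for tid in em.trial_id:
            assert by_id[tid].length == "long"
            assert by_id[tid].correct


class TestScreening:
    def test_fdr_controls_null_leads(self, truth, long_trials):
        """Under the global null the responsive fraction stays near q."""
        rng = np.random.default_rng(2)
        ems = {}
        for k in range(120):
            tc = sg.generate_lead_timecourses("none", long_trials, truth,
                                              seed=rng)
            ems[f"null{k}"] = sg.compute_epoch_means(tc, long_trials)
        out = sg.screen_overall_responsive(ems, q=0.05)
        # BH keeps the expected false-discovery fraction at q; with 120
        # independent null leads the responsive count should be small
        assert out["responsive"].mean() <= 0.05 + 0.05

    def test_sensitivity_on_mixed_cohort(self, truth, long_trials):
        rng = np.random.default_rng(3)
        ems = {}
        labels = {}
        for k in range(20):
            cls = "doubly" if k < 10 else "none"
            tc = sg.generate_lead_timecourses(cls, long_trials, truth,
                                              seed=rng)
            ems[f"l{k}"] = sg.compute_epoch_means(tc, long_trials)
            labels[f"l{k}"] = cls
        out = sg.screen_overall_responsive(ems, q=0.05).set_index("lead_id")
        responsive = out["responsive"]
        hits = sum(responsive[l] for l, c in labels.items() if c == "doubly")
        assert hits >= 9    # sensitivity >= 0.9

    def test_single_lead_huge_effect_survives(self, truth, long_trials):
        tc = sg.generate_lead_timecourses(
            "doubly", long_trials,
            sg.GroundTruth(response_amplitude=10.0), seed=4)
        out = sg.screen_overall_responsive(
            {"big": sg.compute_epoch_means(tc, long_trials)}, q=0.05)
        assert bool(out["responsive"].iloc[0])


class TestClassification:
    @pytest.mark.parametrize("cls", ["doubly", "static", "task"])
    def test_strong_lead_recovers_its_class(self, cls, truth, long_trials):
        big = sg.GroundTruth(response_amplitude=8.0)
        tc = sg.generate_lead_timecourses(cls, long_trials, big, seed=5,
                                          subject_onset=179.0,
                                          subject_duration=104.0)
        em = sg.compute_epoch_means(tc, long_trials)
        got, _ = sg.classify_lead(em)
        assert got == cls

    def test_null_lead_forced_through_is_none(self, truth, long_trials):
        tc = sg.generate_lead_timecourses("none", long_trials, truth, seed=6)
        em = sg.compute_epoch_means(tc, long_trials)
        got, _ = sg.classify_lead(em)
        assert got == "none"

    def test_scale_invariance(self, truth, long_trials):
        tc = sg.generate_lead_timecourses("static", long_trials, truth, seed=7)
        em1 = sg.compute_epoch_means(tc, long_trials)
        scaled = LeadTimeCourses(values=3.7 * tc.values, bin_ms=tc.bin_ms,
                                 t0_offset_ms=tc.t0_offset_ms,
                                 lead_id=tc.lead_id, trial_ids=tc.trial_ids)
        em2 = sg.compute_epoch_means(scaled, long_trials)
        assert sg.classify_lead(em1)[0] == sg.classify_lead(em2)[0]

    def test_too_few_trials_unclassifiable(self, long_trials):
        em = sg.compute_epoch_means(constant_lead(long_trials[:2]
                                                  , 1.0), long_trials[:2])
        got, detail = sg.classify_lead(em)
        assert got == "none"
        assert detail["flags"].get("unclassifiable")

    def test_confusion_matrix_diagonal_dominant(self, truth):
        """Each generator class recovered >= 80% over 200 simulated leads."""
        rng = np.random.default_rng(8)
        tt = sg.generate_trial_table(4, 225.0, seed=9)
        classes = ("doubly", "static", "task", "none")
        recovered = {c: 0 for c in classes}
        n_per = 50
        for cls in classes:
            for k in range(n_per):
                ttb = sg.generate_behavior(tt, truth,
                                           seed=int(rng.integers(2 ** 31)))
                long_t = [t for t in ttb if t.length == "long"]
                tc = sg.generate_lead_timecourses(cls, long_t, truth, seed=rng)
                em = sg.compute_epoch_means(tc, long_t)
                got, _ = sg.classify_lead(em)
                recovered[cls] += (got == cls)
        for cls in classes:
            assert recovered[cls] >= 0.8 * n_per, (cls, recovered)


class TestSpecificityIndices:
    def frame(self, sep_actor, sep_action, vep_actor):
        rows = []
        for i in range(4):
            rows.append({"trial_id": i, "task": "actor", "bep": 0.0,
                         "sep": sep_actor, "vep": vep_actor})
            rows.append({"trial_id": 10 + i, "task": "action", "bep": 0.0,
                         "sep": sep_action, "vep": 0.0})
        return pd.DataFrame(rows)

    def test_simple_ratio(self):
        si = sg.specificity_indices(self.frame(3.0, 1.0, 1.0))
        assert si.r_pa == pytest.approx(0.5)      # (3-1)/(3+1)
        assert si.r_sv == pytest.approx(0.5)

    def test_negative_a2_clamped_to_one(self):
        si = sg.specificity_indices(self.frame(2.0, -0.7, -0.3))
        assert si.r_pa == pytest.approx(1.0)
        assert si.clamped_pa and si.clamped_sv
        assert si.r_sv == pytest.approx(1.0)

    def test_equal_responses_give_zero(self):
        si = sg.specificity_indices(self.frame(2.0, 2.0, 2.0))
        assert si.r_pa == pytest.approx(0.0)
        assert si.r_sv == pytest.approx(0.0)

    def test_zero_sum_undefined(self):
        si = sg.specificity_indices(self.frame(0.0, -1.0, 0.0))
        assert si.undefined_pa and np.isnan(si.r_pa)

    def test_bounds_over_random_inputs(self):
        """For responsive leads (A1 >= 0, the analysis' domain) the clamped
        index is confined to [0, 1], hence to [-1, 1] generally."""
        rng = np.random.default_rng(10)
        for _ in range(200):
            a1 = abs(rng.normal()) * 3
            a2 = rng.normal() * 3
            si = sg.specificity_indices(self.frame(a1, a2, a2))
            if si.undefined_pa:
                continue
            if si.clamped_pa:                 # A2 < 0 clamped => R in [0, 1]
                assert 0.0 <= si.r_pa <= 1.0
            assert -1.0 <= si.r_pa <= 1.0


def test_cohort_classification_frame(truth):
    cohort = sg.make_cohort(n_subjects=2, truth=truth, seed=30,
                            with_mesh=False)
    trials_by_lead = {l.lead_id: cohort.trials[l.subject]
                      for l in cohort.leads}
    recs = sg.classify_cohort(cohort.timecourses, trials_by_lead)
    df = sg.classification_frame(recs)
    assert {"lead_id", "class", "p_task", "r_pa"} <= set(df.columns)
    assert len(df) == len(cohort.leads)
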