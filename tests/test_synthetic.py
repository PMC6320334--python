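"""Generator contracts: trial design, behavior model, trace shapes,
mesh/lead geometry, artifact injection, determinism."""
import numpy as np
import pytest
from scipy import stats

import seegamma as sg


class TestTrialTable:
    def test_counts_and_block_structure(self):
        tt = sg.generate_trial_table(4, 225.0, seed=1)
        assert len(tt) == 256
        assert sum(t.task == "actor" for t in tt) == 128
        # blocks alternate action -> actor
        for t in tt:
            assert t.task == ("action" if t.block % 2 == 0 else "actor")
        # one long and one short sub-block of 32 per block
        for b in range(4):
            block = [t for t in tt if t.block == b]
            assert sum(t.length == "long" for t in block) == 32
            assert sum(t.length == "short" for t in block) == 32

    def test_factorial_spans_64_combinations(self):
        tt = sg.generate_trial_table(4, 225.0, seed=2)
        combos = {tuple(t.factors[k] for k in sg.STIMULUS_FACTORS) for t in tt}
        assert len(combos) == 64

    def test_inversion_splits_halves(self):
        tt = sg.generate_trial_table(4, 225.0, seed=3)
        for t in tt:
            assert t.factors["inversion"] == (t.block >= 2)

    def test_static_durations_from_the_five_values(self):
        tt = sg.generate_trial_table(4, 210.0, seed=4)
        assert {t.static_duration for t in tt} <= set(sg.STATIC_DURATIONS_MS)

    def test_short_truncation_offsets(self):
        thr = 240.0
        tt = sg.generate_trial_table(2, thr, seed=5)
        offs = {t.truncation_offset for t in tt if t.length == "short"}
        assert offs <= {thr - 100.0, thr, thr + 100.0}
        for t in tt:
            if t.length == "long":
                assert t.video_duration == sg.LONG_VIDEO_MS

    @pytest.mark.parametrize("bad", [0, -2])
    def test_nonpositive_blocks_rejected(self, bad):
        with pytest.raises(ValueError):
            sg.generate_trial_table(bad, 225.0)

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            sg.generate_trial_table(4, 190.0)


class TestBehavior:
    def test_zero_slope_removes_duration_dependence(self, truth):
        t0 = sg.GroundTruth(rt_slope={"actor": 0.0, "action": 0.0},
                            rt_resid_sd_ms=0.0)
        tt = sg.generate_trial_table(4, 225.0, seed=6)
        ttb = sg.generate_behavior(tt, t0, seed=7,
                                   subject_effects={"s01": 0.0})
        rts = {}
        for t in ttb:
            if t.task == "actor":
                rts.setdefault(t.static_duration, set()).add(t.rt)
        vals = {v for s in rts.values() for v in s}
        assert len(vals) == 1    # identical RT for all durations

    def test_noise_free_rt_equals_linear_predictor(self):
        t0 = sg.GroundTruth(rt_resid_sd_ms=0.0)
        tt = sg.generate_trial_table(2, 225.0, seed=8)
        ttb = sg.generate_behavior(tt, t0, seed=9,
                                   subject_effects={"s01": 0.0})
        for t in ttb:
            expected = t0.rt_intercept(t.task) + t0.rt_slope[t.task] * t.static_duration
            assert t.rt == pytest.approx(expected)

    def test_default_slope_recovered_on_large_sample(self, truth):
        from seegamma.recovery import simulate_behavior_dataset
        slope, grand_mean, _ = simulate_behavior_dataset(
            n_trials=10_000, seed=21)
        assert slope == pytest.approx(0.14, abs=0.02)
        assert grand_mean == pytest.approx(857.0, abs=40.0)

    def test_missing_coefficients_raise(self):
        t0 = sg.GroundTruth(rt_grand_mean_ms={"actor": 857.0})
        tt = sg.generate_trial_table(2, 225.0, seed=10)
        with pytest.raises(ValueError):
            sg.generate_behavior(tt, t0, seed=1)


class TestTimecourses:
    def test_null_lead_noiseless_mean_nonpositive(self, actor_long_trials,
                                                  noiseless_truth):
        tc = sg.generate_lead_timecourses("none", actor_long_trials,
                                          noiseless_truth, seed=1)
        assert np.all(tc.values <= 0)
        assert tc.flags["normalized"] is False

    def test_doubly_action_suppressed_until_response(self, noiseless_truth):
        tt = sg.generate_trial_table(2, 225.0, seed=13)
        ttb = sg.generate_behavior(tt, noiseless_truth, seed=14)
        action = [t for t in ttb if t.task == "action" and t.length == "long"]
        tc = sg.generate_lead_timecourses("doubly", action, noiseless_truth,
                                          seed=2, bin_ms=25.0)
        c = tc.bin_centers_ms
        for i, tr in enumerate(action):
            window = (c >= 100.0 + noiseless_truth.edge_taper_ms) & (c < tr.rt - 50)
            assert np.all(tc.values[i][window] <= 0)
            assert np.any(tc.values[i][window] < 0)

    def test_task_lead_active_until_response(self, noiseless_truth):
        tt = sg.generate_trial_table(2, 225.0, seed=15)
        ttb = sg.generate_behavior(tt, noiseless_truth, seed=16)
        actor = [t for t in ttb if t.task == "actor" and t.length == "long"]
        tc = sg.generate_lead_timecourses("task", actor, noiseless_truth,
                                          seed=3, bin_ms=25.0,
                                          subject_onset=179.0)
        c = tc.bin_centers_ms
        for i, tr in enumerate(actor):
            window = (c >= 300.0) & (c < tr.rt - noiseless_truth.edge_taper_ms - 25)
            assert np.all(tc.values[i][window] >
                          0.5 * noiseless_truth.response_amplitude)

    def test_baseline_statistics_unit_normal(self, truth, actor_long_trials):
        tc = sg.generate_lead_timecourses("doubly", actor_long_trials * 4,
                                          truth, seed=4, bin_ms=10.0)
        base = tc.values[:, tc.window_mask(sg.BASELINE_WINDOW_MS)]
        assert base.size >= 10_000
        assert abs(base.mean()) < 0.05
        assert abs(base.std() - 1.0) < 0.05

    def test_determinism_same_seed_identical(self, truth, actor_long_trials):
        a = sg.generate_lead_timecourses("doubly", actor_long_trials, truth,
                                         seed=42)
        b = sg.generate_lead_timecourses("doubly", actor_long_trials, truth,
                                         seed=42)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.truth["subject_onset_ms"] == b.truth["subject_onset_ms"]

    def test_negative_coupling_gives_negative_correlation(self, truth):
        """Sign check on ~2000 trials: injected negative gamma-RT coupling
        must surface as a negative empirical trial-wise correlation."""
        tt = sg.generate_trial_table(4, 225.0, seed=17)
        rng = np.random.default_rng(18)
        ms, rts = [], []
        for k in range(32):   # 32 leads x 64 trials ~ 2000 trials
            ttb = sg.generate_behavior(tt, truth, seed=int(rng.integers(2 ** 31)))
            actor = [t for t in ttb if t.task == "actor" and t.length == "long"]
            tc = sg.generate_lead_timecourses("doubly", actor, truth,
                                              seed=rng, hemisphere="right")
            on, du = tc.truth["subject_onset_ms"], tc.truth["subject_duration_ms"]
            win = (tc.bin_centers_ms >= on) & (tc.bin_centers_ms < on + du)
            m = tc.values[:, win].mean(axis=1)
            r = np.array([t.rt for t in actor])
            ms.append((m - m.mean()) / m.std())
            rts.append((r - r.mean()) / r.std())
        r_all = float(np.mean(np.concatenate(ms) * np.concatenate(rts)))
        assert r_all < 0

    def test_unknown_class_rejected(self, truth, actor_long_trials):
        with pytest.raises(ValueError):
            sg.generate_lead_timecourses("bogus", actor_long_trials, truth)

    def test_single_trial_wrapper(self, truth, actor_long_trials):
        g = sg.generate_timecourse("static", actor_long_trials[0], truth,
                                   seed=5)
        assert g.trial_id == actor_long_trials[0].trial_id
        assert g.values.ndim == 1


class TestMeshAndLeads:
    def test_every_lead_has_seven_nodes(self):
        mesh, leads = sg.generate_mesh_and_leads({"ATL-R": 5, "FG": 3}, seed=1)
        assert len(leads) == 8
        for l in leads:
            assert len(l.node_ids) == sg.NODES_PER_LEAD
            assert len(set(l.node_ids)) == sg.NODES_PER_LEAD

    def test_mesh_size_and_topology(self):
        mesh, _ = sg.generate_mesh_and_leads({"ATL-R": 2}, seed=2)
        assert mesh.n_nodes >= 500
        assert np.all(mesh.edge_lengths() > 0)

    def test_regions_geodesically_separated(self):
        from seegamma.topography import geodesic_distances
        mesh, leads = sg.generate_mesh_and_leads({"ATL-L": 2, "FG": 2}, seed=3)
        a = [l for l in leads if l.region == "ATL-L"][0]
        b = [l for l in leads if l.region == "FG"][0]
        d = geodesic_distances(mesh, int(a.node_ids[0]), cutoff=20.0)
        assert all(int(n) not in d for n in b.node_ids)

    def test_empty_request_valid_mesh(self):
        mesh, leads = sg.generate_mesh_and_leads({}, seed=4)
        assert leads == []
        assert mesh.n_nodes >= 500

    def test_capacity_error(self):
        with pytest.raises(ValueError):
            sg.generate_mesh_and_leads({"FG": 60}, seed=5)


class TestIEDInjection:
    def test_rate_zero_and_one(self, truth, long_trials):
        tc = sg.generate_lead_timecourses("none", long_trials[:40], truth,
                                          seed=6)
        _, none_hit = sg.inject_ied_artifacts(tc, long_trials, 0.0, seed=7)
        assert none_hit == set()
        _, all_hit = sg.inject_ied_artifacts(tc, long_trials, 1.0, seed=8)
        assert len(all_hit) == 40

    def test_rate_matches_binomial_interval(self, truth):
        tt = sg.generate_trial_table(16, 225.0, seed=19)    # 1024 trials
        ttb = sg.generate_behavior(tt, truth, seed=20)
        sub = ttb[:1000]
        tc = sg.generate_lead_timecourses("none", sub, truth, seed=9)
        _, hit = sg.inject_ied_artifacts(tc, sub, 0.1, seed=10)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.1)
        assert lo <= len(hit) <= hi

    def test_bad_rate_rejected(self, truth, long_trials):
        tc = sg.generate_lead_timecourses("none", long_trials[:5], truth,
                                          seed=11)
        with pytest.raises(ValueError):
            sg.inject_ied_artifacts(tc, long_trials, 1.5)
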