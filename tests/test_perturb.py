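"""DID quantification, traction-change statistics, and the resampling FDR."""

import numpy as np
import pytest

from edgeforce import perturb, synthdata
from edgeforce.events import EdgeEvent
from edgeforce.pipeline import detect_all_events

DT5 = 5.0


@pytest.fixture(scope="module")
def perturbation_data():
    cfg = synthdata.SynthConfig(frame_interval_s=DT5, n_frames=120, n_depths=1,
                                seed=11)
    ctrl, pert, truth = synthdata.make_perturbation_dataset(
        cfg, offsets_s=(-10.0, -15.0, -20.0, -25.0), effect_um_per_s=0.02,
        n_control=200, n_per_group=60)
    controls = perturb.build_controls(ctrl, dt_s=DT5)
    pevs = detect_all_events(pert, DT5, smoothing_param=1.0)
    ps = truth.event_schedule.query("group == 'perturbed'").set_index("sector")
    t_act = {int(s): float(ps.loc[s, "t_act_s"]) for s in ps.index}
    groups = perturb.group_by_offset(pevs, t_act, controls.mean_t_vmax_s,
                                     (-10.0, -15.0, -20.0, -25.0), dt_s=DT5)
    return ctrl, pert, truth, controls, groups


class TestControls:
    def test_mean_time_to_vmax_matches_schedule(self, perturbation_data):
        ctrl, pert, truth, controls, groups = perturbation_data
        sched = truth.event_schedule.query("group == 'control'")
        expected = float(np.mean(sched["vmax_s"] - sched["onset_s"]))
        assert controls.mean_t_vmax_s == pytest.approx(expected, abs=1.0)

    def test_simple_mean_of_two_times(self):
        evs = [EdgeEvent(1, "protrusion", 0, 10, 20, 2.0, 100.0),
               EdgeEvent(2, "protrusion", 0, 14, 20, 2.0, 100.0)]
        # (10 + 14) / 2 frames * 5 s = 60 s
        t = np.mean([(e.vmax_frame - e.onset_frame) * DT5 for e in evs])
        assert t == 60.0

    def test_no_events_before_activation_raises(self, perturbation_data):
        ctrl = perturbation_data[0]
        with pytest.raises(ValueError):
            perturb.build_controls(ctrl, t_act_s=1.0, dt_s=DT5)


class TestGrouping:
    def _event(self, onset_frame):
        return EdgeEvent(1, "protrusion", onset_frame, onset_frame + 10,
                         onset_frame + 20, 2.0, 100.0)

    def test_exact_offset_assigned(self):
        ev = self._event(10)  # onset 50 s
        groups = perturb.group_by_offset([ev], t_act_s=100.0, mean_t_vmax_s=60.0,
                                         offsets_s=(-10.0, -15.0), dt_s=DT5)
        # delta = 100 - (50 + 60) = -10 exactly
        assert groups[-10.0] == [ev]

    def test_outside_every_tolerance_dropped(self):
        ev = self._event(10)
        # delta = 97.6 - 110 = -12.4; nearest offsets -10/-15 both > 2.5 away? -12.4
        # is 2.4 from -10 -> grouped. Use -12.4 from {-10,-15} with tol 2.0
        groups = perturb.group_by_offset([ev], 97.6, 60.0, (-10.0, -15.0),
                                         tolerance_s=2.0, dt_s=DT5)
        assert all(len(v) == 0 for v in groups.values())

    def test_nearest_within_tolerance_wins(self):
        ev = self._event(10)
        # delta = 97 - 110 = -13 -> nearest is -15 at distance 2 <= 2.5
        groups = perturb.group_by_offset([ev], 97.0, 60.0, (-10.0, -15.0),
                                         tolerance_s=2.5, dt_s=DT5)
        assert groups[-15.0] == [ev]
        assert groups[-10.0] == []

    def test_duplicate_offsets_rejected(self):
        with pytest.raises(ValueError):
            perturb.group_by_offset([], 0.0, 0.0, (-10.0, -10.0))


class TestDID:
    def test_difference_zero_when_groups_equal_control(self, perturbation_data):
        ctrl, pert, truth, controls, groups = perturbation_data
        own = {0.0: controls.events}
        did = perturb.did_curves(own, controls, ctrl, "velocity", dt_s=DT5)
        ok = np.isfinite(did.diffs[0.0])
        assert np.allclose(did.diffs[0.0][ok], 0, atol=1e-9)

    def test_injected_velocity_effect_recovered(self, perturbation_data):
        ctrl, pert, truth, controls, groups = perturbation_data
        did = perturb.did_curves(groups, controls, pert, "velocity", dt_s=DT5)
        from edgeforce.events import bootstrap_ci_mean
        lo, hi = bootstrap_ci_mean(controls.velocity, n_boot=300, seed=0)
        half_width = np.nanmean((hi - lo) / 2)
        t = did.rel_time_s
        for off, diff in did.diffs.items():
            t_act_rel = controls.mean_t_vmax_s + off
            plateau = np.nanmean(diff[(t > t_act_rel + 30) & (t < t_act_rel + 120)])
            assert abs(plateau - 0.02) < max(half_width, 0.005)
            pre = np.nanmean(diff[t < t_act_rel - 10])
            assert abs(pre) < max(half_width, 0.005)

    def test_distance_is_integral_of_velocity_difference(self, perturbation_data):
        ctrl, pert, truth, controls, groups = perturbation_data
        did_v = perturb.did_curves(groups, controls, pert, "velocity", dt_s=DT5)
        did_d = perturb.did_curves(groups, controls, pert, "distance", dt_s=DT5)
        off = -15.0
        v = did_v.diffs[off]
        d = did_d.diffs[off]
        ok = np.isfinite(v) & np.isfinite(d)
        integral = np.cumsum(np.where(ok, v, 0.0)) * DT5
        # compare where both are defined over the common early span
        span = ok & (did_v.rel_time_s < 200)
        assert np.allclose(d[span], integral[span], atol=0.05)


class TestTractionChange:
    def test_ratio_arithmetic(self):
        series = np.concatenate([np.full(13, 100.0), np.full(48, 150.0)])
        out = perturb.traction_change_cellwise([series] * 3, t_act_s=60.0, dt_s=5.0)
        assert out["mean_ratio"] == pytest.approx(1.5)

    def test_no_change_not_significant(self):
        rng = np.random.default_rng(0)
        cells = [np.full(61, 100.0) + rng.normal(0, 1, 61) for _ in range(20)]
        out = perturb.traction_change_cellwise(cells, t_act_s=60.0, dt_s=5.0)
        assert out["mean_ratio"] == pytest.approx(1.0, abs=0.01)
        assert out["p"] > 0.05

    def test_fifty_percent_step_detected(self):
        rng = np.random.default_rng(1)
        cells = []
        for _ in range(20):
            base = 100.0 * (1 + rng.normal(0, 0.05))
            s = np.full(61, base)
            s[12:] *= 1.5  # step at activation
            cells.append(s + rng.normal(0, base * 0.05, 61))
        out = perturb.traction_change_cellwise(cells, t_act_s=60.0, dt_s=5.0)
        assert out["mean_ratio"] == pytest.approx(1.5, abs=0.1)
        assert out["p"] < 0.01

    def test_windowwise_step_detected(self):
        # one movie: early events in half the sectors serve as phase-matched
        # controls, late events start just before activation; the perturbed
        # sectors get a +30 Pa traction step at activation
        import pandas as pd
        rng = np.random.default_rng(13)
        dt, T = DT5, 120
        t_act = 300.0
        frames = np.arange(T)
        rows, evts = [], []
        for sector in range(1, 21):
            perturbed = sector > 10
            onset_s = 290.0 if perturbed else 50.0
            onset_f = int(onset_s / dt)
            force = 100.0 + rng.normal(0, 2.0, T)
            if perturbed:
                # force builds after induction starts
                force[frames * dt > t_act] += 30.0
            rows.append(pd.DataFrame({
                "sector": sector, "depth": 2, "frame": frames,
                "time_s": frames * dt, "traction_pa": force}))
            evts.append(EdgeEvent(sector, "protrusion", onset_f, onset_f + 10,
                                  onset_f + 24, 2.0, 120.0))
        table = pd.concat(rows, ignore_index=True)
        out = perturb.traction_change_windowwise(
            table, evts, t_act_s=t_act, horizon_s=120.0, depth=2, dt_s=dt)
        assert out["diff"] == pytest.approx(30.0, abs=5.0)
        assert out["p"] < 0.01

    def test_windowwise_zero_effect_group_means_agree(self):
        import pandas as pd
        rng = np.random.default_rng(14)
        dt, T = DT5, 120
        t_act = 300.0
        frames = np.arange(T)
        rows, evts = [], []
        for sector in range(1, 21):
            onset_s = 290.0 if sector > 10 else 50.0
            onset_f = int(onset_s / dt)
            force = 100.0 + rng.normal(0, 2.0, T)
            rows.append(pd.DataFrame({
                "sector": sector, "depth": 2, "frame": frames,
                "time_s": frames * dt, "traction_pa": force}))
            evts.append(EdgeEvent(sector, "protrusion", onset_f, onset_f + 10,
                                  onset_f + 24, 2.0, 120.0))
        out = perturb.traction_change_windowwise(
            pd.concat(rows, ignore_index=True), evts, t_act_s=t_act,
            horizon_s=120.0, depth=2, dt_s=dt)
        assert abs(out["diff"]) < 5.0
        assert out["p"] > 0.01

    def test_missing_perturbed_group_raises(self, perturbation_data):
        ctrl = perturbation_data[0]
        cevs = detect_all_events(ctrl, DT5, smoothing_param=1.0)
        with pytest.raises(ValueError):
            perturb.traction_change_windowwise(ctrl, cevs, t_act_s=1e6, dt_s=DT5)


class TestFDR:
    def test_storey_qvalues_bounded_and_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 2000)
        q = perturb.storey_qvalues(p)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_null_not_significant(self):
        rng = np.random.default_rng(1)
        res = perturb.fdr_resampling(rng.normal(0, 1, (300, 25)),
                                     rng.normal(0, 1, (50, 25)),
                                     n_iter=500, seed=2)
        assert not res.significant

    def test_three_sd_shift_significant(self):
        rng = np.random.default_rng(1)
        res = perturb.fdr_resampling(rng.normal(0, 1, (300, 25)),
                                     rng.normal(3, 1, (50, 25)),
                                     n_iter=500, seed=2)
        assert res.significant
        assert res.mean_grouped_q < 0.01

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        C = rng.normal(0, 1, (100, 10))
        P = rng.normal(0, 1, (20, 10))
        a = perturb.fdr_resampling(C, P, n_iter=200, seed=7)
        b = perturb.fdr_resampling(C, P, n_iter=200, seed=7)
        assert np.array_equal(a.q_grouped, b.q_grouped)
        assert a.threshold == b.threshold and a.significant == b.significant

    def test_low_iteration_count_warns_in_metadata(self):
        rng = np.random.default_rng(5)
        res = perturb.fdr_resampling(rng.normal(0, 1, (40, 8)),
                                     rng.normal(0, 1, (10, 8)),
                                     n_iter=50, seed=0)
        assert res.warnings

    def test_control_smaller_than_perturbed_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            perturb.fdr_resampling(rng.normal(0, 1, (10, 5)),
                                   rng.normal(0, 1, (20, 5)), n_iter=100, seed=0)
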