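"""Smoothing, event detection with the distance/duration filters, z-scoring,
event-aligned ensembles, and bootstrap CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgeforce import events, synthdata
from edgeforce.pipeline import detect_all_events

DT = 10.0


class TestSmoothing:
    def test_param_one_interpolates(self):
        y = np.sin(np.arange(20) / 3.0) + 0.2
        assert np.allclose(events.smooth_series(y, 1.0, DT), y, atol=1e-8)

    def test_param_to_zero_approaches_least_squares_line(self):
        rng = np.random.default_rng(0)
        y = 0.5 * np.arange(30) + rng.normal(0, 1, 30)
        out = events.smooth_series(y, 1e-9, 1.0)
        x = np.arange(30.0)
        A = np.column_stack([x, np.ones_like(x)])
        line = A @ np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.allclose(out, line, atol=1e-3)

    def test_linear_ramp_reproduced_exactly_for_any_param(self):
        ramp = 0.3 * np.arange(25) + 2.0
        for p in (0.1, 0.5, 0.9):
            assert np.allclose(events.smooth_series(ramp, p, DT), ramp, atol=1e-6)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            events.smooth_series(np.ones(3), 0.5, DT)


class TestDetection:
    def test_sinusoid_closed_form(self):
        t = np.arange(0, 1200, DT)
        disp = 2.0 * np.sin(2 * np.pi * t / 240.0)
        evs = events.detect_events(disp, DT)
        inner = [e for e in evs if e.onset_frame > 0 and e.end_frame < t.size - 1]
        assert inner, "expected interior phases"
        for e in inner:
            assert e.distance_um == pytest.approx(4.0, rel=1e-6)
            assert e.duration_s == pytest.approx(120.0)
        # Vmax at the zero crossing with speed 2*(2*pi/240) ~ 0.052 um/s
        v = np.gradient(disp, DT)
        e = inner[0]
        assert abs(v[e.vmax_frame]) == pytest.approx(0.052, abs=0.002)

    def test_distance_filter_discards_small_phases(self):
        t = np.arange(0, 1200, DT)
        disp = 0.4 * np.sin(2 * np.pi * t / 240.0)  # peak-to-peak 0.8 um
        assert events.detect_events(disp, DT) == []

    def test_duration_filter_discards_short_phases(self):
        t = np.arange(0, 1200, DT)
        disp = 2.0 * np.sin(2 * np.pi * t / 80.0)  # phase length 40 s
        assert events.detect_events(disp, DT) == []

    def test_thresholds_are_inclusive(self):
        # exactly 1.0 um over exactly 60 s is retained
        t = np.arange(0, 200, DT)
        phase = np.clip((t - 20) / 60.0, 0, 1)
        disp = 1.0 * 0.5 * (1 - np.cos(np.pi * phase))
        evs = events.detect_events(disp, DT)
        assert len(evs) == 1
        assert evs[0].distance_um == pytest.approx(1.0)
        assert evs[0].duration_s == pytest.approx(60.0)

    def test_monotone_drift_below_threshold_yields_nothing(self):
        disp = np.linspace(0, 0.9, 50)
        assert events.detect_events(disp, DT) == []

    def test_phases_tile_the_timeline(self):
        rng = np.random.default_rng(4)
        disp = events.smooth_series(np.cumsum(rng.normal(0, 0.3, 80)), 0.3, DT)
        kept, dropped = events.detect_events(disp, DT, return_discarded=True)
        spans = sorted((e.onset_frame, e.end_frame) for e in kept + dropped)
        for (a1, b1), (a2, b2) in zip(spans[:-1], spans[1:]):
            assert b1 <= a2  # no overlap (flat stretches may separate phases)

    @given(st.floats(min_value=0.5, max_value=3.0))
    @settings(max_examples=20, deadline=None)
    def test_raising_distance_threshold_never_keeps_more(self, thr):
        rng = np.random.default_rng(11)
        disp = events.smooth_series(np.cumsum(rng.normal(0, 0.4, 100)), 0.3, DT)
        n_lo = len(events.detect_events(disp, DT, min_distance_um=thr))
        n_hi = len(events.detect_events(disp, DT, min_distance_um=thr + 0.5))
        assert n_hi <= n_lo


class TestZNormalize:
    def test_zero_mean_unit_sd(self):
        z = events.znormalize(np.array([1.0, 4.0, 2.0, 8.0]))
        assert np.mean(z) == pytest.approx(0, abs=1e-12)
        assert np.std(z) == pytest.approx(1, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            events.znormalize(np.full(10, 3.0))

    @given(st.floats(min_value=0.1, max_value=10), st.floats(-5, 5))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.array([0.0, 1.0, 3.0, -2.0, 5.0])
        assert np.allclose(events.znormalize(a * x + b), events.znormalize(x))


class TestEnsembles:
    def test_single_event_mean_equals_its_slab(self, default_table):
        table, truth, cfg = default_table
        evs = detect_all_events(table, DT, smoothing_param=1.0)
        one = [e for e in evs if e.type == "protrusion"][:1]
        ens = events.align_ensembles(table, one, "protrusion_onset",
                                     signal="rac1", dt_s=DT)
        assert ens.n_events == 1
        assert np.allclose(ens.mean, ens.values[0], equal_nan=True)

    def test_anchor_time_zero_is_anchor_frame(self, default_table):
        table, truth, cfg = default_table
        evs = detect_all_events(table, DT, smoothing_param=1.0)
        ens = events.align_ensembles(table, evs, "protrusion_vmax",
                                     signal="velocity_um_per_s", dt_s=DT,
                                     znorm=False)
        i0 = np.argmin(np.abs(ens.rel_time_s))
        assert ens.rel_time_s[i0] == 0.0
        # at the Vmax anchor the (unnormalized) velocity is near its peak
        d1 = ens.mean[0]
        assert abs(np.nanargmax(np.abs(d1)) - i0) <= 1

    def test_rac1_lead_recovered_at_onset_anchor(self, default_table):
        table, truth, cfg = default_table
        evs = detect_all_events(table, DT, smoothing_param=1.0)
        ens = events.align_ensembles(table, evs, "protrusion_onset",
                                     signal="rac1", dt_s=DT)
        depth2 = ens.mean[list(ens.depths).index(2)]
        peak = ens.rel_time_s[np.nanargmax(depth2)]
        assert abs(peak - (-cfg.rac1_to_onset_lead_s)) <= 10.0

    def test_rac1_nadir_at_protrusion_vmax(self, default_table):
        table, truth, cfg = default_table
        evs = detect_all_events(table, DT, smoothing_param=1.0)
        ens = events.align_ensembles(table, evs, "protrusion_vmax",
                                     signal="rac1", dt_s=DT)
        depth2 = ens.mean[list(ens.depths).index(2)]
        assert abs(ens.rel_time_s[np.nanargmin(depth2)]) <= 10.0


class TestBootstrap:
    def test_identical_events_zero_width(self):
        data = np.tile(np.arange(10.0), (6, 1))
        lo, hi = events.bootstrap_ci_mean(data, n_boot=200, seed=0)
        assert np.allclose(lo, hi)

    def test_width_matches_normal_theory(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 1, (100, 20))
        lo, hi = events.bootstrap_ci_mean(data, n_boot=2000, seed=1)
        width = np.mean(hi - lo)
        expected = 2 * 1.96 / np.sqrt(100)
        assert abs(width - expected) / expected < 0.2

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 1, (30, 8))
        a = events.bootstrap_ci_mean(data, n_boot=300, seed=7)
        b = events.bootstrap_ci_mean(data, n_boot=300, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestAlignmentQC:
    def _table(self):
        cfg = synthdata.SynthConfig(
            n_sectors=12, n_frames=40, n_depths=5, seed=6,
            noise_sd={"rac1": 0.2, "rhoa": 0.2, "force_pa": 0.5})
        table, _ = synthdata.make_window_series(cfg)
        return table

    def test_clean_movie_unflagged(self):
        report = events.refine_temporal_alignment(self._table())
        assert not report["flagged"].any()

    def test_duplicated_frame_flagged(self):
        table = self._table()
        dup = table[table.frame == 20].assign(frame=21)
        table = table[table.frame != 21]
        table = (
            __import__("pandas").concat([table, dup]).sort_values(
                ["sector", "depth", "frame"]).reset_index(drop=True))
        report = events.refine_temporal_alignment(table)
        assert report.loc[report.frame == 21, "flagged"].all()

    def test_sector_shuffled_frame_flagged(self):
        table = self._table().copy()
        rng = np.random.default_rng(0)
        # corrupt the frame whose depth-5 traction profile is most structured
        wide = table[table.depth == 5].pivot_table(
            index="frame", columns="sector", values="traction_pa")
        target = int(wide.index[np.argmax(wide.to_numpy().std(axis=1))])
        sel = table.frame == target
        sectors = table.loc[sel, "sector"].to_numpy()
        perm = {s: p for s, p in zip(np.unique(sectors),
                                     rng.permutation(np.unique(sectors)))}
        table.loc[sel, "sector"] = [perm[s] for s in sectors]
        table = table.sort_values(["sector", "depth", "frame"]).reset_index(drop=True)
        report = events.refine_temporal_alignment(table)
        assert report.loc[report.frame == target, "flagged"].all()
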