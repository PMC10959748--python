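"""Eye speed, threshold finding, fixation detection, object labelling."""

import numpy as np
import pandas as pd
import pytest

from socoop import gaze as G
from socoop.bundle import GazeTrack
from socoop.config import AnalysisConfig, DEFAULT_CONFIG
from socoop.synth import (PlannedFixation, simulate_gaze,
                          random_fixation_plan, OBJECT_POSITIONS)


def make_track(xs, ys, valid=None, hz=30.0):
    n = len(xs)
    t = np.arange(n) * (1000.0 / hz)
    v = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, bool)
    return GazeTrack(t=t, x_px=np.asarray(xs, float),
                     y_px=np.asarray(ys, float), valid=v)


class TestEyeSpeed:
    def test_stationary_gaze_zero_speed(self):
        tr = make_track([100] * 10, [200] * 10)
        sp = G.eye_speed(tr)
        assert (sp.speed == 0).all()

    def test_ninety_px_jump_is_about_150_deg_per_s(self):
        # 90 px horizontal ~ 5 deg; over one 33.3 ms frame ~ 150 deg/s
        tr = make_track([100, 190], [200, 200])
        sp = G.eye_speed(tr)
        assert sp.speed.iloc[0] == pytest.approx(150.0, rel=0.05)

    def test_matches_per_sample_oracle(self, rng):
        xs = rng.uniform(0, 640, 30)
        ys = rng.uniform(0, 480, 30)
        tr = make_track(xs, ys)
        sp = G.eye_speed(tr)
        kx, ky = DEFAULT_CONFIG.px_per_deg
        for i in range(1, 30):
            d = np.hypot((xs[i] - xs[i - 1]) / kx, (ys[i] - ys[i - 1]) / ky)
            want = d / ((tr.t[i] - tr.t[i - 1]) / 1000.0)
            assert sp.speed.iloc[i - 1] == pytest.approx(want, rel=1e-9)

    def test_invalid_samples_produce_no_speed(self):
        valid = [True, True, False, True, True]
        tr = make_track([0, 10, 0, 30, 40], [0] * 5, valid=valid)
        sp = G.eye_speed(tr)
        # 4 valid samples -> 3 speed values; the gap pair is non-contiguous
        assert len(sp) == 3
        assert not sp.contiguous.iloc[1]

    def test_px_deg_round_trip_within_one_pixel(self):
        kx, ky = DEFAULT_CONFIG.px_per_deg
        for px in (1, 90, 333):
            deg = px / kx
            assert abs(deg * kx - px) < 1.0

    def test_five_degrees_is_about_90_by_80_px(self):
        kx, ky = DEFAULT_CONFIG.px_per_deg
        assert 5 * kx == pytest.approx(90, abs=4)
        assert 5 * ky == pytest.approx(80, abs=6)


class TestSpeedThreshold:
    def _bimodal(self, rng, lo=5.0, hi=150.0, n=3000):
        return np.concatenate([
            lo * np.exp(rng.normal(0, 0.2, n)),
            hi * np.exp(rng.normal(0, 0.2, n))])

    def test_separates_synthetic_modes(self, rng):
        s = self._bimodal(rng)
        thr = G.find_speed_threshold(s)
        assert 5.0 < thr < 150.0
        labels_true = np.r_[np.zeros(3000), np.ones(3000)]
        labels_got = (s >= thr).astype(int)
        assert (labels_true == labels_got).mean() >= 0.99

    def test_threshold_scales_with_modes(self, rng):
        s = self._bimodal(rng)
        t1 = G.find_speed_threshold(s)
        t2 = G.find_speed_threshold(2.0 * s)
        assert t2 / t1 == pytest.approx(2.0, rel=0.1)

    def test_otsu_alternative_also_separates_modes(self, rng):
        s = self._bimodal(rng)
        thr = G.find_speed_threshold(s, method="otsu")
        assert 5.0 < thr < 150.0
        labels = (s >= thr).astype(int)
        truth = np.r_[np.zeros(3000), np.ones(3000)]
        assert (labels == truth).mean() >= 0.99

    def test_unimodal_falls_back_with_warning(self, rng):
        s = 20.0 * np.exp(rng.normal(0, 0.1, 2000))
        with pytest.warns(UserWarning, match="not bimodal|default"):
            thr = G.find_speed_threshold(s)
        assert thr == DEFAULT_CONFIG.default_speed_threshold_deg_s


class TestDetectFixations:
    def _track_with_dwell(self, n_slow):
        """Fast samples, then n_slow stationary samples, then fast."""
        rngl = np.random.default_rng(0)
        xs, ys = [], []
        pos = np.array([320.0, 240.0])
        for _ in range(8):
            pos = pos + rngl.uniform(80, 120, 2) * rngl.choice([-1, 1], 2)
            pos = np.clip(pos, 10, 470)
            xs.append(pos[0]); ys.append(pos[1])
        xs += [200.0] * n_slow; ys += [200.0] * n_slow
        pos = np.array([200.0, 200.0])
        for _ in range(8):
            pos = pos + rngl.uniform(80, 120, 2) * rngl.choice([-1, 1], 2)
            pos = np.clip(pos, 10, 470)
            xs.append(pos[0]); ys.append(pos[1])
        return make_track(xs, ys)

    def test_150ms_dwell_detected(self):
        fx = G.detect_fixations(self._track_with_dwell(6), threshold=40.0)
        assert len(fx) == 1
        assert fx[0].duration >= 100

    def test_90ms_dwell_not_detected(self):
        # 3 stationary samples = 2 sub-threshold intervals = 67 ms < 100 ms
        fx = G.detect_fixations(self._track_with_dwell(3), threshold=40.0)
        assert fx == []

    def test_fixations_disjoint_ordered_and_long_enough(self, rng):
        plan = random_fixation_plan(60, 60_000, rng)
        track, _, _ = simulate_gaze(plan, 60_000, rng)
        thr = G.find_speed_threshold(G.eye_speed(track).speed.to_numpy())
        fx = G.detect_fixations(track, thr)
        for a, b in zip(fx, fx[1:]):
            assert a.offset <= b.onset
        assert all(f.duration >= 100 for f in fx)

    def test_recovery_f1_on_planned_fixations(self, rng):
        plan = random_fixation_plan(300, 300_000, rng)
        track, _, truth = simulate_gaze(plan, 300_000, rng)
        thr = G.find_speed_threshold(G.eye_speed(track).speed.to_numpy())
        fx = G.detect_fixations(track, thr)
        real = [(d["onset"], d["offset"]) for d in truth
                if not d["sub_threshold"]]
        used, tp = set(), 0
        for r0, r1 in real:
            for i, f in enumerate(fx):
                if i in used:
                    continue
                ov = min(r1, f.offset) - max(r0, f.onset)
                if ov >= 0.5 * (r1 - r0):
                    tp += 1
                    used.add(i)
                    break
        prec = tp / len(fx)
        rec = tp / len(real)
        f1 = 2 * prec * rec / (prec + rec)
        assert f1 >= 0.95


class TestAssignObject:
    def _setup(self, rng, obj="tray", n=600):
        plan = [PlannedFixation(500, 200, obj)]
        track, objects, _ = simulate_gaze(plan, 3000, rng, valid_fraction=1.0)
        fx = G.detect_fixations(track, 40.0)
        assert fx
        return fx[0], track, objects

    def test_crosshair_on_tray_is_view_reward(self, rng):
        f, track, objects = self._setup(rng, "tray")
        assert G.assign_object(f, track, objects, "V4").kind == "view_reward"

    def test_partner_within_aperture_is_view_partner(self, rng):
        # crosshair 3 deg from the partner's head; V4 aperture 5 deg wide
        f, track, objects = self._setup(rng, "partner_head")
        kx, _ = DEFAULT_CONFIG.px_per_deg
        objects = objects.copy()
        sel = objects.object == "partner_head"
        objects.loc[sel, "x_px"] += 2.0 * kx   # 2 deg off centre < 2.5 radius
        got = G.assign_object(f, track, objects, "V4")
        assert got.kind == "view_partner"

    def test_far_object_unlabelled(self, rng):
        f, track, objects = self._setup(rng, "floor")
        objects = objects.copy()
        objects["x_px"] += 400.0   # push everything ~20 deg away
        assert G.assign_object(f, track, objects, "V4").kind is None

    def test_row_order_invariant(self, rng):
        f, track, objects = self._setup(rng, "tray")
        shuffled = objects.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = G.assign_object(f, track, objects, "V4").kind
        b = G.assign_object(f, track, shuffled, "V4").kind
        assert a == b


class TestFixationRates:
    def test_definitional_rate(self, tiny_bundle):
        from socoop.bundle import EventRecord
        tr = tiny_bundle.trials[0]
        evs = [EventRecord("view_reward", tr.t_start + 500 + i * 1000,
                           tr.t_start + 650 + i * 1000, tr.trial_id)
               for i in range(4)]
        df = G.fixation_rates(evs, tiny_bundle)
        trial_time = sum((t.t_coop - t.t_start) / 1000
                        for t in tiny_bundle.trials)
        row = df[(df.object == "view_reward") & (df.window == "trial")]
        assert row.rate_hz.iloc[0] == pytest.approx(4 / trial_time)

    def test_null_rates_give_high_wilcoxon_p(self, rng):
        # identical trial and intertrial rates across sessions: p ~ 1
        dfs = []
        for _ in range(10):
            dfs.append(pd.DataFrame([
                {"object": "view_reward", "window": "trial", "n": 5,
                 "rate_hz": 0.2},
                {"object": "view_reward", "window": "intertrial", "n": 5,
                 "rate_hz": 0.2}]))
        res = G.compare_fixation_rates(dfs, "view_reward")
        assert res["p"] == 1.0
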