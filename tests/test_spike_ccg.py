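"""Spike-train cross-correlograms: raw, normalized, shuffle-corrected."""

import numpy as np
import pytest

from socoop import spike_ccg as C
from socoop.config import AnalysisConfig


def raw_oracle(seg, max_lag):
    """Double-loop spike-time coincidence counting, by definition."""
    m, t = seg.x_j.shape
    vals = np.zeros(2 * max_lag + 1)
    for i in range(m):
        tj = np.flatnonzero(seg.x_j[i])
        tk = np.flatnonzero(seg.x_k[i])
        for a in tj:
            for b in tk:
                lag = b - a
                if -max_lag <= lag <= max_lag:
                    vals[lag + max_lag] += 1
    return vals / m


def poisson_segments(rng, m=40, t=400, rate_hz=30.0, kind=None):
    p = rate_hz / 1000.0
    return C.SpikeSegmentSet((rng.random((m, t)) < p).astype(np.int8),
                             (rng.random((m, t)) < p).astype(np.int8),
                             event_kind=kind)


def coupled_segments(rng, lag, prob, m=60, t=400, rate_hz=40.0, kind=None,
                     jitter=0):
    p = rate_hz / 1000.0
    xj = (rng.random((m, t)) < p).astype(np.int8)
    xk = (rng.random((m, t)) < p).astype(np.int8)
    for i in range(m):
        src = np.flatnonzero(xj[i])
        src = src[rng.random(src.size) < prob]
        if jitter:
            src = src + rng.integers(-jitter, jitter + 1, src.size)
        dst = src + lag
        dst = dst[(dst >= 0) & (dst < t)]
        xk[i, dst] = 1
    return C.SpikeSegmentSet(xj, xk, event_kind=kind)


class TestRawCcg:
    def test_identical_single_spike_trains(self):
        m = 5
        x = np.zeros((m, 50), dtype=np.int8)
        x[:, 20] = 1
        seg = C.SpikeSegmentSet(x, x)
        lags, vals = C.raw_ccg(seg, 10)
        assert vals[lags == 0][0] == pytest.approx(1.0)
        assert vals[lags != 0].sum() == 0

    def test_shifted_copy_concentrates_at_lag(self):
        rng = np.random.default_rng(0)
        x = (rng.random((10, 200)) < 0.05).astype(np.int8)
        y = np.roll(x, 20, axis=1)
        y[:, :20] = 0
        seg = C.SpikeSegmentSet(x, y)
        lags, vals = C.raw_ccg(seg, 30)
        assert lags[np.argmax(vals)] == 20

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 5))
            t = int(rng.integers(30, 200))
            seg = C.SpikeSegmentSet(
                (rng.random((m, t)) < 0.08).astype(np.int8),
                (rng.random((m, t)) < 0.08).astype(np.int8))
            max_lag = int(rng.integers(5, min(t - 1, 40)))
            lags, vals = C.raw_ccg(seg, max_lag)
            np.testing.assert_allclose(vals, raw_oracle(seg, max_lag),
                                       atol=1e-12)

    def test_conservation_of_total_coincidences(self, rng):
        t = 80
        seg = C.SpikeSegmentSet(
            (rng.random((6, t)) < 0.1).astype(np.int8),
            (rng.random((6, t)) < 0.1).astype(np.int8))
        lags, vals = C.raw_ccg(seg, t - 1)
        total = sum(int(seg.x_j[i].sum()) * int(seg.x_k[i].sum())
                    for i in range(6)) / 6
        assert vals.sum() == pytest.approx(total)

    def test_antisymmetry_under_pair_swap(self, rng):
        seg = poisson_segments(rng, m=10, t=150)
        lags, v1 = C.raw_ccg(seg, 50)
        swapped = C.SpikeSegmentSet(seg.x_k, seg.x_j)
        _, v2 = C.raw_ccg(swapped, 50)
        np.testing.assert_allclose(v1, v2[::-1], atol=1e-12)


class TestNormalizedCcg:
    def test_triangle_endpoints(self):
        t = 100
        lags = np.arange(-(t - 1), t)
        theta = t - np.abs(lags)
        assert theta[lags == 0][0] == t
        assert theta[0] == 1 and theta[-1] == 1

    def test_independent_poisson_flat_near_zero(self, rng):
        seg = poisson_segments(rng, m=100, t=600, rate_hz=40.0)
        ccg = C.normalized_ccg(seg, max_lag=150)
        # corrected CCG is flat: no lag deviates far from 0
        assert np.abs(ccg.corrected).max() < 0.02
        assert abs(np.mean(ccg.corrected)) < 1e-3

    def test_event_locked_rate_structure_removed(self, rng):
        # identical segments across trials: all correlation is event-locked,
        # the shuffle predictor removes it entirely
        t = 300
        x = (rng.random(t) < 0.06).astype(np.int8)
        y = (rng.random(t) < 0.06).astype(np.int8)
        seg = C.SpikeSegmentSet(np.tile(x, (20, 1)), np.tile(y, (20, 1)))
        ccg = C.normalized_ccg(seg, max_lag=100)
        np.testing.assert_allclose(ccg.corrected, 0.0, atol=1e-9)

    def test_rate_doubling_leaves_peak_stable(self, rng):
        peaks = []
        for rate in (15.0, 60.0):   # 4x range
            vals = []
            for rep in range(6):
                seg = coupled_segments(np.random.default_rng(100 + rep),
                                       lag=3, prob=0.25, m=80, t=400,
                                       rate_hz=rate)
                ccg = C.normalized_ccg(seg, max_lag=100)
                vals.append(ccg.corrected[ccg.lags == 3][0])
            peaks.append(np.mean(vals))
        assert peaks[1] == pytest.approx(peaks[0], rel=0.25)

    def test_silent_unit_signalled(self):
        x = np.zeros((5, 100), dtype=np.int8)
        y = np.ones((5, 100), dtype=np.int8)
        with pytest.raises(ValueError, match="silent"):
            C.normalized_ccg(C.SpikeSegmentSet(x, y), max_lag=10)


class TestSignificance:
    def test_injected_within_area_lag_recovered(self, rng):
        hits = 0
        for rep in range(10):
            seg = coupled_segments(np.random.default_rng(rep), lag=3,
                                   prob=0.2, jitter=1)
            ccg = C.normalized_ccg(seg, max_lag=150)
            v = C.ccg_significance(ccg, "within", is_fixation=False)
            if v.significant and abs(v.peak_lag_ms - 3) <= 1:
                hits += 1
        assert hits >= 9

    def test_injected_inter_area_lag_recovered(self, rng):
        seg = coupled_segments(rng, lag=40, prob=0.25, m=80)
        ccg = C.normalized_ccg(seg, max_lag=150)
        v = C.ccg_significance(ccg, "inter", is_fixation=False)
        assert v.significant
        assert abs(v.peak_lag_ms - 40) <= 1

    def test_coupling_outside_window_not_significant(self, rng):
        # +40 ms coupling cannot produce a within-area (0-6 ms) detection
        seg = coupled_segments(rng, lag=40, prob=0.3, m=80)
        ccg = C.normalized_ccg(seg, max_lag=150)
        v = C.ccg_significance(ccg, "within", is_fixation=False)
        assert not v.significant

    def test_null_false_positive_rate_calibrated(self):
        n_sig = 0
        n = 150
        for rep in range(n):
            seg = poisson_segments(np.random.default_rng(1000 + rep),
                                   m=40, t=400)
            ccg = C.normalized_ccg(seg, max_lag=150)
            v = C.ccg_significance(ccg, "within", is_fixation=False)
            n_sig += v.significant
        assert n_sig / n <= 0.01

    def test_tail_band_must_fit_in_lag_range(self, rng):
        seg = poisson_segments(rng, m=10, t=200)
        ccg = C.normalized_ccg(seg, max_lag=60)
        with pytest.raises(ValueError, match="tail"):
            C.ccg_significance(ccg, "within", is_fixation=False)


class TestSessionCoordination:
    def test_constructed_negative_lags_dominate(self, rng):
        # all couplings dlPFC -> V4 (negative lag: dlPFC leads)
        from socoop.synth import (simulate_neural_session, default_units,
                                  SpikeSimParams, CoupledPair, tuned_gains)
        units = default_units(2, 2)
        params = SpikeSimParams(
            event_gains=tuned_gains(units, rng),
            coupled_pairs=[CoupledPair("pfc_00", "v4_00", 0.3, 25),
                           CoupledPair("pfc_01", "v4_01", 0.3, 30)])
        b, _ = simulate_neural_session(5, rng, n_trials=12, units=units,
                                       spike_params=params)
        summaries = C.session_coordination(b, event_kinds=("view_partner",))
        inter = [s for s in summaries if s.area_pairing == "V4-dlPFC"][0]
        assert inter.n_significant >= 1
        assert all(l < 0 for l in inter.peak_lags_ms)

    def test_session_without_significant_pairs_reports_nan(self, rng):
        from socoop.synth import (simulate_neural_session, default_units,
                                  SpikeSimParams)
        b, _ = simulate_neural_session(
            1, rng, n_trials=4, units=default_units(1, 1),
            spike_params=SpikeSimParams(event_gains={}))
        summaries = C.session_coordination(b, event_kinds=("view_reward",))
        inter = [s for s in summaries if s.area_pairing == "V4-dlPFC"][0]
        if inter.n_significant == 0:
            assert np.isnan(inter.mean_coordination)
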