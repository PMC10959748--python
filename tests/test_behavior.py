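"""Push coordination: CCGs, conditional probabilities, delays."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from socoop import behavior
from socoop.behavior import (push_ccg, conditional_cooperation,
                             DegenerateSeriesError)
from socoop.synth import DyadSimParams, simulate_dyad_behavior


def ccg_oracle(a, b):
    """Shifted-overlap coincidence counting, normalized, by definition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    L = len(a)
    norm = np.sqrt((a * a).sum() * (b * b).sum())
    lags = range(-(L - 1), L)
    vals = []
    for lag in lags:
        total = 0.0
        for t in range(L):
            if 0 <= t + lag < L:
                total += a[t] * b[t + lag]
        vals.append(total / norm)
    return np.array(list(lags)), np.array(vals)


binary_series = st.lists(st.integers(0, 1), min_size=2, max_size=50).filter(
    lambda s: sum(s) > 0)


class TestPushCcg:
    def test_identical_series_peak_one_at_zero(self):
        s = np.array([0, 1, 1, 0, 1])
        c = push_ccg(s, s)
        assert c.peak == pytest.approx(1.0)
        assert c.peak_lag == 0

    def test_partner_delayed_twenty_bins_means_self_leads(self):
        # self leads by 2 s: peak at positive lag +20 bins
        s = np.zeros(60)
        s[[5, 6, 7, 20, 21]] = 1
        p = np.roll(s, 20)
        c = push_ccg(s, p)
        assert c.peak_lag == 20
        assert c.peak == pytest.approx(1.0)

    def test_disjoint_support_near_zero(self):
        a = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        b = np.array([0, 0, 0, 0, 0, 0, 1, 1])
        c = push_ccg(a, b)
        # zero at every lag that cannot align the two blocks
        for lag, v in zip(c.lags, c.values):
            if not (4 <= lag <= 7):
                assert v == pytest.approx(0.0)

    def test_all_zero_series_signalled(self):
        with pytest.raises(DegenerateSeriesError):
            push_ccg(np.zeros(5), np.ones(5))

    @given(binary_series, binary_series)
    def test_matches_bruteforce_oracle(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        if a.sum() == 0 or b.sum() == 0:
            return
        c = push_ccg(a, b)
        lags, vals = ccg_oracle(a, b)
        np.testing.assert_allclose(c.values, vals, atol=1e-12)
        np.testing.assert_array_equal(c.lags, lags)

    @given(binary_series)
    def test_zero_lag_autocorrelation_is_one(self, s):
        c = push_ccg(np.array(s), np.array(s))
        assert c.values[c.lags == 0][0] == pytest.approx(1.0)


class TestConditionalCooperation:
    def test_hand_counted_example(self):
        probs = conditional_cooperation(np.array([1, 1, 0, 1]),
                                        np.array([1, 0, 0, 1]))
        assert probs["p_self_given_part"] == pytest.approx(1.0)
        assert probs["p_part_given_self"] == pytest.approx(2 / 3)

    def test_identical_series_give_one(self):
        s = np.array([0, 1, 1])
        probs = conditional_cooperation(s, s)
        assert probs["p_self_given_part"] == 1.0
        assert probs["p_part_given_self"] == 1.0

    def test_disjoint_series_give_zero(self):
        probs = conditional_cooperation(np.array([1, 0]), np.array([0, 1]))
        assert probs["p_self_given_part"] == 0.0

    @given(binary_series, binary_series)
    def test_bayes_consistency(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n], float), np.array(b[:n], float)
        if a.sum() == 0 or b.sum() == 0:
            return
        probs = conditional_cooperation(a, b)
        lhs = probs["p_self_given_part"] * b.mean()
        rhs = probs["p_part_given_self"] * a.mean()
        assert lhs == pytest.approx(rhs, abs=1e-12)


@pytest.fixture(scope="module")
def study():
    params = DyadSimParams(n_sessions=6, trials_per_session=(60, 60), seed=11)
    return params, simulate_dyad_behavior(params)


class TestSessionCoordination:

    def test_scheduled_peaks_recovered(self, study):
        params, bundles = study
        for b in bundles:
            sc = behavior.session_push_coordination(b)
            target = params.coordination_schedule[b.session_index - 1]
            assert sc.peak == pytest.approx(target, abs=0.05)
            assert sc.peak_lag_ms == params.lag_schedule_ms[b.session_index - 1]

    def test_shuffle_preserves_push_counts(self, study, rng):
        _, bundles = study
        b = bundles[0]
        trial = b.trials[0]
        series = behavior.trial_push_series(b, trial)
        shuffled = {m: rng.permutation(s) for m, s in series.items()}
        for m in series:
            assert shuffled[m].sum() == series[m].sum()

    def test_actual_peak_exceeds_shuffled(self, study):
        _, bundles = study
        sc = behavior.session_push_coordination(bundles[-1])
        assert sc.peak > sc.shuffled_peak

    def test_independent_pushing_matches_shuffle(self, rng):
        params = DyadSimParams(n_sessions=1, trials_per_session=(80, 80),
                               coordination_schedule=[0.0],
                               lag_schedule_ms=[0], delay_schedule_ms=[500.0],
                               seed=3)
        b = simulate_dyad_behavior(params)[0]
        sc = behavior.session_push_coordination(b)
        assert sc.peak == pytest.approx(sc.shuffled_peak, abs=0.08)

    def test_delay_schedule_recovered_as_negative_trend(self):
        from socoop.stats import learning_trend
        params = DyadSimParams(n_sessions=8, trials_per_session=(60, 60),
                               seed=21)
        bundles = simulate_dyad_behavior(params)
        delays = [behavior.session_delays(b)["self"] for b in bundles]
        res = learning_trend(delays)
        assert res.slope < 0
        assert res.regression_p < 0.05


class TestDelays:
    def test_first_push_bin_thirty_gives_three_seconds(self, rng):
        params = DyadSimParams(n_sessions=1, seed=1)
        b = simulate_dyad_behavior(params)[0]
        trial = b.trials[0]
        series = behavior.trial_push_series(b, trial)
        first_bin = np.flatnonzero(series["self"])[0]
        d = behavior.delay_to_cooperate(b, trial)
        assert d["self"] == first_bin * 100.0

    def test_push_in_first_bin_means_zero_delay(self, tiny_bundle):
        tr = tiny_bundle.trials[0]
        bw = tiny_bundle.config.push_bin_ms
        tiny_bundle.pushes["self"][tr.t_start // bw] = 1
        assert behavior.delay_to_cooperate(tiny_bundle, tr)["self"] == 0.0
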