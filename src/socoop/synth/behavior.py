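"""Synthetic dyadic push behavior with scheduled coordination targets.

The self-monkey pushes in bouts after a session-scheduled response delay;
the partner echoes a Bernoulli-thinned copy of the self series at the
session's scheduled lag.  With copy probability c the coefficient-
normalized cross-correlogram peak converges to sqrt(c) at the scheduled
lag, so targets are hit by copying with probability target**2.  Setting a
target of 0 makes the partner push independently (null case).
"""

from __future__ import annotations

import numpy as np

from ..bundle import SessionBundle, TrialWindow
from ..config import AnalysisConfig, DEFAULT_CONFIG
from .params import DyadSimParams

ITI_MS = 20_000   # intertrial interval between cooperation trials


def _bout_series(n_bins: int, first_push: int, bout_mean: float,
                 gap_mean: float, rng: np.random.Generator) -> np.ndarray:
    """Alternating push-bout / gap binary series starting at ``first_push``."""
    s = np.zeros(n_bins, dtype=np.int8)
    t = min(first_push, n_bins)
    pushing = True
    while t < n_bins:
        length = 1 + rng.geometric(1.0 / bout_mean)
        if pushing:
            s[t:t + length] = 1
        t += length
        pushing = not pushing
    return s


def simulate_trial_pushes(n_bins: int, target_peak: float, lag_bins: int,
                          mean_delay_bins: float, params: DyadSimParams,
                          rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray]:
    """One trial's (self, partner) push series at 100 ms resolution."""
    if lag_bins >= n_bins:
        raise ValueError("push lag exceeds the trial length")
    first = int(rng.exponential(max(mean_delay_bins, 0.1)))
    # self stops early enough that every echoed push fits in the trial
    self_s = _bout_series(max(n_bins - lag_bins, 1), first,
                          params.bout_mean_bins, params.gap_mean_bins, rng)
    self_s = np.pad(self_s, (0, n_bins - len(self_s)))
    partner = np.zeros(n_bins, dtype=np.int8)
    if target_peak <= 0:
        partner = _bout_series(n_bins, int(rng.exponential(
            max(mean_delay_bins, 0.1))) + lag_bins,
            params.bout_mean_bins, params.gap_mean_bins, rng)
    else:
        copy_prob = target_peak ** 2
        src = np.flatnonzero(self_s)
        copied = src[rng.random(src.size) < copy_prob] + lag_bins
        copied = copied[copied < n_bins]
        partner[copied] = 1
    return self_s, partner


def simulate_dyad_session(params: DyadSimParams, session_index: int,
                          rng: np.random.Generator,
                          config: AnalysisConfig = DEFAULT_CONFIG
                          ) -> SessionBundle:
    """Assemble one behavior-only session bundle (trials + push series)."""
    s = session_index - 1
    target = params.coordination_schedule[s]
    lag_bins = params.lag_schedule_ms[s] // config.push_bin_ms
    delay_bins = params.delay_schedule_ms[s] / config.push_bin_ms
    n_trials = int(rng.integers(params.trials_per_session[0],
                                params.trials_per_session[1] + 1))
    bw = config.push_bin_ms
    n_bins = params.trial_bins
    trials: list[TrialWindow] = []
    self_all: list[np.ndarray] = []
    part_all: list[np.ndarray] = []
    t = 0
    for trial_id in range(1, n_trials + 1):
        a, b = simulate_trial_pushes(n_bins, target, lag_bins, delay_bins,
                                     params, rng)
        both = np.flatnonzero((a == 1) & (b == 1))
        t_start = t
        t_end = t_start + n_bins * bw
        t_coop = int(t_start + both[0] * bw + bw) if both.size else None
        trials.append(TrialWindow(trial_id, t_start, t_coop, t_end,
                                  t_end + ITI_MS))
        self_all.append(a)
        part_all.append(b)
        t = t_end + ITI_MS
    n_total_bins = t // bw
    series = {"self": np.zeros(n_total_bins, dtype=np.int8),
              "partner": np.zeros(n_total_bins, dtype=np.int8)}
    for tr, a, b in zip(trials, self_all, part_all):
        b0 = tr.t_start // bw
        series["self"][b0:b0 + n_bins] = a
        series["partner"][b0:b0 + n_bins] = b
    return SessionBundle(session_index=session_index, pair_id="sim_pair",
                         trials=trials, pushes=series, gaze=None,
                         objects=None, events=[], spikes=[], units=[],
                         config=config).validate()


def simulate_dyad_behavior(params: DyadSimParams,
                           config: AnalysisConfig = DEFAULT_CONFIG
                           ) -> list[SessionBundle]:
    """All sessions of a simulated learning study (behavior only)."""
    rng = np.random.default_rng(params.seed)
    return [simulate_dyad_session(params, s, rng, config)
            for s in range(1, params.n_sessions + 1)]
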