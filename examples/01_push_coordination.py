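"""Dyadic push coordination across a simulated learning study.

Simulates 8 sessions of two monkeys' button pushes with a scheduled rise
in coordination, then recovers the session CCG peak, its lag, the shuffle
control, conditional cooperation probabilities, and the delay trend.
"""

import numpy as np

from socoop import behavior
from socoop.stats import learning_trend, percent_change
from socoop.synth import DyadSimParams, simulate_dyad_behavior

params = DyadSimParams(n_sessions=8, trials_per_session=(80, 100), seed=1)
bundles = simulate_dyad_behavior(params)

peaks, delays, cond = [], [], []
print("session  peak  lag_ms  shuffled  P(self|part)  delay_self_ms")
for b in bundles:
    sc = behavior.session_push_coordination(b)
    probs = behavior.session_conditional_cooperation(b)
    d = behavior.session_delays(b)
    peaks.append(sc.peak)
    delays.append(d["self"])
    cond.append(probs["p_self_given_part"])
    print(f"{b.session_index:7d}  {sc.peak:.2f}  {sc.peak_lag_ms:6d}  "
          f"{sc.shuffled_peak:8.2f}  {probs['p_self_given_part']:12.2f}  "
          f"{d['self']:13.0f}")

tr = learning_trend(peaks)
print(f"\npeak coordination trend: slope {tr.slope:+.3f}/session, "
      f"r = {tr.pearson_r:.2f}, p = {tr.regression_p:.2g}")
print(f"delay change first->last session: "
      f"{100 * percent_change(delays[0], delays[-1]):+.0f}%")
print("\nA rising peak with a shrinking lag means the pair pushes together")
print("more and the leader-follower gap closes -- the learning signature.")
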