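"""Chronic-unit stability from waveform-shape Mahalanobis distances.

Simulates waveform clusters for 12 electrodes over 5 sessions, replacing
the neuron on a third of the electrodes mid-series, and recovers which
units stayed stable using the 7-PC Mahalanobis criterion with the
5th-percentile within-session threshold.
"""

import numpy as np

from socoop.stability import (classify_channel_stability, waveform_pca,
                              stable_fraction_percent)
from socoop.synth import WaveformPlan, simulate_waveforms

plan = WaveformPlan(n_electrodes=12, n_sessions=5,
                    replaced_at={1: 3, 2: 3, 3: 4, 4: 4}, seed=4)
waveforms, meta, truth = simulate_waveforms(plan)

clouds = waveform_pca(waveforms, meta)
report = classify_channel_stability(clouds)

print(f"distance threshold (5th pct of within-session pairs): "
      f"{report.threshold:.2f}")
for area in sorted(report.n_total):
    n_s, n_t = report.n_stable.get(area, 0), report.n_total[area]
    print(f"{area}: {n_s}/{n_t} stable unit-sessions "
          f"({stable_fraction_percent(n_s, n_t):.0f}%)")
true_frac = float(np.mean(list(truth.values())))
got_frac = sum(report.n_stable.values()) / sum(report.n_total.values())
print(f"planted stable fraction {true_frac:.2f}, recovered {got_frac:.2f}")
print("\nA cross-session distance below the within-session distinct-neuron")
print("5th percentile says the electrode kept recording the same cell.")
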