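"""Shuffle-corrected spike-timing cross-correlograms.

Simulates a session with an injected V4 -> dlPFC coupling at +25 ms during
social-cue fixations, computes normalized CCGs in coincidences per spike,
and applies the 4.5-SD significance criterion in the inter-areal 15-60 ms
lag window.
"""

import numpy as np

from socoop import spike_ccg as C
from socoop.synth import (CoupledPair, SpikeSimParams, default_units,
                          simulate_neural_session, tuned_gains)

rng = np.random.default_rng(7)
units = default_units(2, 2)
params = SpikeSimParams(
    event_gains=tuned_gains(units, rng),
    coupled_pairs=[CoupledPair("v4_00", "pfc_00", 0.3, 25)])
bundle, _ = simulate_neural_session(1, rng, n_trials=12, units=units,
                                    spike_params=params)

onsets = np.array([e.onset for e in bundle.events_of("view_partner")], float)
window = C.event_segment_window("view_partner", "V4", "dlPFC")
seg = C.segments_from_trains(bundle.spike_train("v4_00").times,
                             bundle.spike_train("pfc_00").times,
                             onsets, window, event_kind="view_partner")
ccg = C.normalized_ccg(seg)
verdict = C.ccg_significance(ccg, "inter")
print(f"coupled V4-dlPFC pair, {seg.m} fixation segments of {seg.t} ms:")
print(f"  peak {verdict.peak:.4f} coincidences/spike at "
      f"{verdict.peak_lag_ms:+d} ms (injected +25 ms)")
print(f"  noise SD {verdict.noise_sd:.5f}; significant: "
      f"{verdict.significant} (criterion: peak > 4.5 x SD)")

summaries = C.session_coordination(bundle, event_kinds=("view_partner",))
print("\nsession summary (mean coordination = mean significant-pair peak):")
for s in summaries:
    mc = "nan" if np.isnan(s.mean_coordination) else f"{s.mean_coordination:.4f}"
    print(f"  {s.area_pairing:12} {s.event_kind:13} mean {mc:>7} "
          f"({s.n_significant}/{s.n_pairs} significant)")
print("\nPositive inter-areal peak lags mean V4 spikes lead dlPFC spikes,")
print("the feedforward direction of the visuo-frontal pathway.")
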