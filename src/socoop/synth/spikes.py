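"""Event-locked inhomogeneous Poisson spike trains with injected coupling.

Each unit fires at a baseline rate modulated multiplicatively around events
it is tuned to (gain applied from the unit's visual delay for the response
window).  Pairwise coupling is injected by duplicating a stated fraction of
the source unit's spikes into the target at a fixed lag, jittered by +-1 ms,
which yields a known cross-correlogram peak at the injected lag.
"""

from __future__ import annotations

import numpy as np

from ..bundle import EventRecord, SpikeTrain, UnitMeta, CHOICE_KINDS
from ..config import AnalysisConfig, DEFAULT_CONFIG
from ..responses import response_window
from .params import SpikeSimParams


def rate_profile(unit: UnitMeta, gains: dict[str, float],
                 events: list[EventRecord], total_ms: int,
                 baseline_hz: float,
                 config: AnalysisConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Per-1 ms-bin firing rate (Hz) over the session for one unit."""
    rate = np.full(total_ms, baseline_hz)
    for ev in events:
        g = gains.get(ev.kind)
        if g is None or g == 1.0:
            continue
        lo, hi = response_window(ev.kind, unit.area, config)
        a = max(int(ev.onset + lo), 0)
        b = min(int(ev.onset + hi), total_ms)
        if b > a:
            rate[a:b] *= g
    return rate


def sample_poisson_train(rate_hz: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Bernoulli-per-1 ms-bin sampling of an inhomogeneous Poisson train."""
    p = np.clip(rate_hz / 1000.0, 0.0, 1.0)
    hits = np.flatnonzero(rng.random(p.size) < p)
    return hits.astype(float) + 0.5   # spike at bin centre


def simulate_spikes(params: SpikeSimParams, units: list[UnitMeta],
                    events: list[EventRecord], total_ms: int,
                    rng: np.random.Generator | None = None,
                    config: AnalysisConfig = DEFAULT_CONFIG
                    ) -> list[SpikeTrain]:
    """Spike trains for all units, with event gains and injected coupling."""
    rng = rng or np.random.default_rng(params.seed)
    lo, hi = params.baseline_rate_hz
    trains: dict[str, np.ndarray] = {}
    for unit in units:
        base = float(rng.uniform(lo, hi))
        gains = params.event_gains.get(unit.unit_id, {})
        rate = rate_profile(unit, gains, events, total_ms, base, config)
        trains[unit.unit_id] = sample_poisson_train(rate, rng)
    for cp in params.coupled_pairs:
        src = trains[cp.unit_i]
        if cp.event_kinds is not None:
            mask = np.zeros(len(src), dtype=bool)
            for ev in events:
                if ev.kind in cp.event_kinds:
                    if ev.kind in CHOICE_KINDS:
                        w0, w1 = ev.onset - config.ccg_segment_pre_choice_ms, ev.onset
                    else:
                        d = config.visual_delay_ms["interareal_fixation"]
                        w0 = ev.onset + d
                        w1 = w0 + config.ccg_segment_post_fixation_ms
                    mask |= (src >= w0) & (src < w1)
            src = src[mask]
        chosen = src[rng.random(src.size) < cp.coincidence_prob]
        jitter = rng.integers(-params.jitter_ms, params.jitter_ms + 1,
                              size=chosen.size)
        injected = chosen + cp.lag_ms + jitter
        injected = injected[(injected >= 0) & (injected < total_ms)]
        tgt = np.concatenate([trains[cp.unit_j], injected])
        trains[cp.unit_j] = np.unique(np.sort(tgt))
    return [SpikeTrain(uid, np.sort(t)) for uid, t in trains.items()]
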