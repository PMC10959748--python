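"""Parameter records and ground truth for the synthetic study generator.

Defaults emulate the study conditions: 18 learning sessions of 100-130
cooperation trials, push series in 100 ms bins whose coincident-push peak
climbs from ~0.6 to ~0.9 across sessions, 30 Hz gaze with a bimodal speed
profile and 60-85% valid frames, four-state social-event sequences from a
row-stochastic transition matrix, event-locked Poisson spike trains with
injected pairwise coupling (within-area 0-6 ms lags, inter-areal 15-60 ms),
and per-channel waveform clusters with stable and replaced units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np


def _linspace(a: float, b: float, n: int) -> list[float]:
    return list(np.linspace(a, b, n))


@dataclass
class DyadSimParams:
    n_sessions: int = 18
    trials_per_session: tuple[int, int] = (100, 130)
    trial_bins: int = 120                      # 100 ms bins per trial epoch
    coordination_schedule: list[float] = None  # target session CCG peak
    lag_schedule_ms: list[int] = None          # partner's lag behind self
    delay_schedule_ms: list[float] = None      # mean self delay to first push
    bout_mean_bins: float = 4.0
    gap_mean_bins: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_sessions
        if self.coordination_schedule is None:
            self.coordination_schedule = _linspace(0.6, 0.9, n)
        if self.lag_schedule_ms is None:
            self.lag_schedule_ms = [int(v) for v in
                                    np.round(np.linspace(2000, 300, n), -2)]
        if self.delay_schedule_ms is None:
            self.delay_schedule_ms = _linspace(3000, 300, n)
        for name in ("coordination_schedule", "lag_schedule_ms",
                     "delay_schedule_ms"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have {n} entries")
        if any(not 0 <= c <= 1 for c in self.coordination_schedule):
            raise ValueError("coincidence targets must lie in [0, 1]")
        if any(l >= self.trial_bins * 100 for l in self.lag_schedule_ms):
            raise ValueError("push lag exceeds the trial duration")


@dataclass
class CoupledPair:
    unit_i: str
    unit_j: str
    coincidence_prob: float   # fraction of source spikes duplicated
    lag_ms: int
    event_kinds: tuple[str, ...] | None = None  # None = always on

    def __post_init__(self) -> None:
        if not 0 <= self.coincidence_prob <= 1:
            raise ValueError("coincidence probability must lie in [0, 1]")


@dataclass
class SpikeSimParams:
    n_units_v4: int = 6
    n_units_pfc: int = 6
    baseline_rate_hz: tuple[float, float] = (8.0, 20.0)
    event_gains: dict = field(default_factory=dict)
    # unit_id -> {event_kind: multiplicative gain}; filled by the session
    # builder when not given
    coupled_pairs: list[CoupledPair] = field(default_factory=list)
    jitter_ms: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.baseline_rate_hz
        if lo <= 0 or hi < lo:
            raise ValueError("baseline rates must be positive and ordered")


@dataclass
class WaveformPlan:
    """Marks each (electrode, unit slot) stable or replaced at a session."""
    n_electrodes: int = 8
    n_sessions: int = 4
    n_waveforms: int = 100
    samples_per_waveform: int = 40
    noise_sd: float = 0.05            # relative to template amplitude 1
    replaced_at: dict[int, int] = field(default_factory=dict)
    # electrode -> session index (>= 2) at which a new neuron appears
    seed: int = 0


@dataclass
class GroundTruth:
    """Everything needed to score the downstream stages without re-simulation."""
    coordination_schedule: list[float] | None = None
    lag_schedule_ms: list[int] | None = None
    delay_schedule_ms: list[float] | None = None
    transition_matrix: list[list[float]] | None = None
    fixations: list[dict] | None = None        # onset, offset, kind, sub_threshold
    stable_links: dict[str, bool] | None = None  # "elec:sa->sb" -> same neuron?
    coupled_pairs: list[dict] | None = None
    event_gains: dict | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))
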