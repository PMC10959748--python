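"""Analysis constants shared by every pipeline stage.

All times are integer milliseconds from session start; intervals are
half-open ``[onset, offset)``.  The defaults are the study constants: 100 ms
push bins, 1 ms spike bins, a 100 ms minimum fixation, area-specific visual
delays (60 ms V4, 80 ms dlPFC, 80 ms for inter-areal fixation CCGs), a
130 ms fixation response window, a 1000 ms pre-push response window, a
baseline drawn 4.5 s before trial start, FDR at alpha = 0.01, a 4.5-SD CCG
significance criterion, and the 0-6 ms / 15-60 ms lag windows for
within-area and inter-areal spike coordination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping


@dataclass(frozen=True)
class AnalysisConfig:
    push_bin_ms: int = 100
    spike_bin_ms: int = 1
    fixation_min_ms: int = 100
    visual_delay_ms: Mapping[str, int] = field(
        default_factory=lambda: {"V4": 60, "dlPFC": 80, "interareal_fixation": 80}
    )
    fixation_response_ms: int = 130
    push_response_ms: int = 1000
    baseline_offset_ms: int = 4500
    fdr_alpha: float = 0.01
    ccg_sd_threshold: float = 4.5
    within_area_lag_ms: tuple[int, int] = (0, 6)
    inter_area_lag_ms: tuple[int, int] = (15, 60)
    ccg_max_lag_ms: int = 150
    ccg_tail_gap_ms: int = 60            # tail band offset, non-fixation events
    ccg_tail_gap_fixation_ms: int = 25   # tail band offset, fixation events
    ccg_segment_pre_choice_ms: int = 800
    ccg_segment_post_fixation_ms: int = 200
    min_fixations_per_session: int = 30
    svm_iterations: int = 100
    cv_folds: int = 10
    # gaze geometry: 640 x 480 px scene frame spans 35 x 28 degrees
    frame_px: tuple[int, int] = (640, 480)
    frame_deg: tuple[float, float] = (35.0, 28.0)
    gaze_hz: float = 30.0
    default_speed_threshold_deg_s: float = 40.0
    rf_diameter_deg: Mapping[str, float] = field(
        default_factory=lambda: {"V4": 5.0, "dlPFC": 9.0}
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("push_bin_ms", "spike_bin_ms", "fixation_min_ms",
                     "fixation_response_ms", "push_response_ms",
                     "baseline_offset_ms", "ccg_max_lag_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for lo, hi in (self.within_area_lag_ms, self.inter_area_lag_ms):
            if not (0 <= lo <= hi):
                raise ValueError("lag windows must satisfy 0 <= lo <= hi")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")

    @property
    def px_per_deg(self) -> tuple[float, float]:
        """(horizontal, vertical) pixels per degree of visual angle."""
        return (self.frame_px[0] / self.frame_deg[0],
                self.frame_px[1] / self.frame_deg[1])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["visual_delay_ms"] = dict(self.visual_delay_ms)
        d["rf_diameter_deg"] = dict(self.rf_diameter_deg)
        return d


DEFAULT_CONFIG = AnalysisConfig()
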