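"""Synthetic 30 Hz gaze tracks with labelled object tracks and ground truth.

Planned fixations place the crosshair on the target object's pixel track
with small per-frame jitter (slow mode); the samples between fixations jump
across the frame (fast mode), making the eye-speed distribution bimodal.
Dwells shorter than the 100 ms minimum are recorded in the ground truth as
sub-threshold and must not be detected downstream.  Frame drops (invalid
samples, zeroed coordinates) are placed outside planned fixations, where
the tracker loses the crosshair during rapid movement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..bundle import GazeTrack
from ..config import AnalysisConfig, DEFAULT_CONFIG

# scene-camera object positions (px) in the 640 x 480 frame
OBJECT_POSITIONS = {
    "tray": (110.0, 260.0),
    "dispenser": (90.0, 200.0),
    "partner_head": (430.0, 180.0),
    "partner_body": (450.0, 300.0),
    "self_button": (230.0, 400.0),
    "floor": (330.0, 430.0),
}


@dataclass(frozen=True)
class PlannedFixation:
    onset_ms: int
    duration_ms: int
    object_name: str

    @property
    def sub_threshold(self) -> bool:
        return self.duration_ms < 100


def simulate_gaze(plan: list[PlannedFixation], total_ms: int,
                  rng: np.random.Generator,
                  valid_fraction: float = 0.75,
                  fix_jitter_px: float = 1.5,
                  saccade_px: tuple[float, float] = (80.0, 160.0),
                  config: AnalysisConfig = DEFAULT_CONFIG
                  ) -> tuple[GazeTrack, pd.DataFrame, list[dict]]:
    """Build (gaze track, object tracks, ground-truth fixation list).

    A planned fixation of duration d occupies ``floor(d / frame) + 1``
    consecutive frames on the target object, so a 100 ms plan yields three
    sub-threshold speed intervals (detectable) and a 90 ms plan only two
    (not detectable).
    """
    frame_ms = 1000.0 / config.gaze_hz
    t = np.arange(0.0, total_ms, frame_ms)
    n = len(t)
    x = np.empty(n)
    y = np.empty(n)
    in_fix = np.zeros(n, dtype=bool)
    # fast mode everywhere, then overwrite fixation frames
    lo, hi = saccade_px
    pos = np.array([320.0, 240.0])
    for i in range(n):
        step = rng.uniform(lo, hi)
        ang = rng.uniform(0, 2 * np.pi)
        pos = pos + step * np.array([np.cos(ang), np.sin(ang)])
        pos = np.clip(pos, [5.0, 5.0], [635.0, 475.0])
        x[i], y[i] = pos
    truth = []
    for pf in sorted(plan, key=lambda p: p.onset_ms):
        if pf.object_name not in OBJECT_POSITIONS:
            raise ValueError(f"unknown object {pf.object_name!r}")
        i0 = int(np.ceil(pf.onset_ms / frame_ms))
        k = int(pf.duration_ms // frame_ms) + 1
        i1 = min(i0 + k, n)
        ox, oy = OBJECT_POSITIONS[pf.object_name]
        x[i0:i1] = ox + rng.normal(0, fix_jitter_px, i1 - i0)
        y[i0:i1] = oy + rng.normal(0, fix_jitter_px, i1 - i0)
        in_fix[i0:i1] = True
        truth.append({"onset": int(round(t[i0])) if i0 < n else pf.onset_ms,
                      "offset": int(round(t[min(i1, n) - 1])),
                      "kind": pf.object_name,
                      "sub_threshold": pf.sub_threshold})
    # frame drops outside fixations (and not adjacent, to keep speeds clean)
    pad = np.convolve(in_fix.astype(int), np.ones(3, dtype=int), "same") > 0
    droppable = np.flatnonzero(~pad)
    n_drop = int((1.0 - valid_fraction) * n)
    drop = rng.choice(droppable, size=min(n_drop, droppable.size), replace=False)
    valid = np.ones(n, dtype=bool)
    valid[drop] = False
    x[~valid] = 0.0
    y[~valid] = 0.0

    rows = []
    for name, (ox, oy) in OBJECT_POSITIONS.items():
        for ti in t:
            rows.append({"t": ti, "object": name, "x_px": ox, "y_px": oy})
    objects = pd.DataFrame(rows)
    return GazeTrack(t=t, x_px=x, y_px=y, valid=valid), objects, truth


def random_fixation_plan(n_fixations: int, total_ms: int,
                         rng: np.random.Generator,
                         objects: tuple[str, ...] = ("tray", "partner_head",
                                                     "self_button", "floor"),
                         duration_range_ms: tuple[int, int] = (100, 250),
                         ) -> list[PlannedFixation]:
    """Non-overlapping fixation plan with >= 2 movement frames between dwells."""
    plan = []
    t = 100.0
    spacing = (total_ms - 400) / max(n_fixations, 1)
    for _ in range(n_fixations):
        if t + duration_range_ms[1] + 100 > total_ms:
            break
        dur = int(rng.integers(*duration_range_ms))
        plan.append(PlannedFixation(int(t), dur, str(rng.choice(objects))))
        t += max(dur + 150.0, spacing)
    return plan
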