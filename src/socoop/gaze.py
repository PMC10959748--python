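"""Fixation detection and object assignment from the head-mounted eye tracker.

The 30 Hz crosshair track (scene-camera pixels) is converted to eye speed in
deg/s via the frame geometry (a 640 x 480 px scene frame spans 35 x 28 deg).
The session speed distribution is bimodal -- slow drift during fixations,
fast saccade jumps -- and a fixation is a >= 100 ms run of sub-threshold
speed, the threshold sitting at the density valley between the two modes.
Each fixation is then labelled with the object whose scene-camera track
falls inside a receptive-field-sized aperture around the gaze crosshair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .bundle import EventRecord, GazeTrack, SessionBundle
from .config import AnalysisConfig, DEFAULT_CONFIG
from .stats import wilcoxon_signed_rank

# object label -> event kind; partner body parts all map to view_partner
OBJECT_KIND = {
    "tray": "view_reward", "dispenser": "view_reward", "pellet": "view_reward",
    "partner": "view_partner", "partner_head": "view_partner",
    "partner_body": "view_partner", "partner_ear": "view_partner",
    "partner_face": "view_partner",
    "self_button": "view_button", "button": "view_button",
    "floor": "view_random",
}
# precedence when several objects sit inside the aperture at once
KIND_PRECEDENCE = ("view_partner", "view_reward", "view_button", "view_random")


@dataclass(frozen=True)
class Fixation:
    onset: int
    offset: int
    x_px: float
    y_px: float
    kind: str | None = None   # filled by assign_object

    @property
    def duration(self) -> int:
        return self.offset - self.onset


def px_to_deg(dx_px: float, dy_px: float,
              config: AnalysisConfig = DEFAULT_CONFIG) -> float:
    """Euclidean visual-angle magnitude (deg) of a pixel displacement."""
    kx, ky = config.px_per_deg
    return float(np.hypot(dx_px / kx, dy_px / ky))


def eye_speed(track: GazeTrack,
              config: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Eye speed (deg/s) between consecutive valid samples.

    Invalid samples (dropped crosshair, coordinates zeroed by the tracker)
    produce no speed value; each returned row carries the timestamp of the
    later sample of its pair and whether the pair was consecutive frames.
    Returns columns ``t``, ``speed``, ``contiguous``.
    """
    v = track.valid.astype(bool)
    idx = np.flatnonzero(v)
    if idx.size < 2:
        warnings.warn("fewer than 2 valid gaze samples; empty speed series")
        return pd.DataFrame(columns=["t", "speed", "contiguous"])
    kx, ky = config.px_per_deg
    t = track.t[idx]
    dx = np.diff(track.x_px[idx]) / kx
    dy = np.diff(track.y_px[idx]) / ky
    dt_s = np.diff(t) / 1000.0
    speed = np.hypot(dx, dy) / dt_s
    frame_ms = 1000.0 / config.gaze_hz
    contiguous = np.diff(t) <= 1.5 * frame_ms
    return pd.DataFrame({"t": t[1:], "speed": speed, "contiguous": contiguous})


def find_speed_threshold(speeds: np.ndarray,
                         config: AnalysisConfig = DEFAULT_CONFIG,
                         method: str = "kde_valley") -> float:
    """Speed threshold separating the bimodal eye-speed distribution.

    ``kde_valley`` (default) evaluates a kernel density estimate on
    log10(speed) and takes the density minimum between the two largest
    modes ("conservative": the lowest such minimum if several).  ``otsu``
    maximizes between-class variance on log-speed instead.  A unimodal
    distribution triggers the configured fallback threshold with a warning.
    """
    s = np.asarray(speeds, dtype=float)
    s = s[np.isfinite(s) & (s > 0)]
    if s.size < 100:
        warnings.warn("too few speed samples; using default threshold")
        return config.default_speed_threshold_deg_s
    logs = np.log10(s)
    if method == "otsu":
        return float(10 ** _otsu(logs))
    if method != "kde_valley":
        raise ValueError(f"unknown threshold method {method!r}")
    grid = np.linspace(logs.min(), logs.max(), 512)
    dens = gaussian_kde(logs)(grid)
    # local maxima / minima of the KDE curve
    d = np.diff(dens)
    maxima = np.flatnonzero((np.hstack([d, -1]) < 0) & (np.hstack([1, d]) > 0))
    if maxima.size < 2:
        warnings.warn("speed distribution not bimodal; using default threshold")
        return config.default_speed_threshold_deg_s
    top2 = sorted(sorted(maxima, key=lambda i: dens[i], reverse=True)[:2])
    lo, hi = top2
    valleys = lo + np.flatnonzero(
        (np.hstack([d[lo:hi], 1]) > 0) & (np.hstack([-1, d[lo:hi]]) < 0))
    if valleys.size == 0:
        valley = lo + int(np.argmin(dens[lo:hi + 1]))
    else:
        valley = int(valleys.min())   # conservative: lower minimum
    return float(10 ** grid[valley])


def _otsu(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: maximize between-class variance of a 1-D sample."""
    hist, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist / hist.sum()
    w0 = np.cumsum(w)
    w1 = 1.0 - w0
    mu = np.cumsum(w * centers)
    mu_t = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        between = (mu_t * w0 - mu) ** 2 / (w0 * w1)
    between[~np.isfinite(between)] = -np.inf
    return float(centers[int(np.argmax(between))])


def detect_fixations(track: GazeTrack, threshold: float,
                     config: AnalysisConfig = DEFAULT_CONFIG) -> list[Fixation]:
    """Maximal sub-threshold runs of eye speed lasting >= the minimum duration.

    Gaps of a single invalid frame inside a run are bridged; longer gaps
    split the run.  Fixation extent is [first sample, last sample + frame).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    frame_ms = 1000.0 / config.gaze_hz
    sp = eye_speed(track, config)
    if sp.empty:
        return []
    # mark each valid sample as slow if the speed into it is sub-threshold
    slow_t = sp.t[(sp.speed < threshold) & sp.contiguous].to_numpy()
    if slow_t.size == 0:
        return []
    fixations: list[Fixation] = []
    run_start = slow_t[0]
    prev = slow_t[0]
    max_gap = 2.5 * frame_ms   # bridges one missing frame, splits on >= 2
    for t in slow_t[1:]:
        if t - prev > max_gap:
            _close_run(fixations, track, run_start, prev, frame_ms, config)
            run_start = t
        prev = t
    _close_run(fixations, track, run_start, prev, frame_ms, config)
    return fixations


def _close_run(out: list[Fixation], track: GazeTrack, t0: float, t1: float,
               frame_ms: float, config: AnalysisConfig) -> None:
    onset = int(round(t0 - frame_ms))   # speed at t covers (t - frame, t]
    offset = int(round(t1))
    if offset - onset < config.fixation_min_ms:
        return
    m = (track.t >= onset) & (track.t <= offset) & track.valid.astype(bool)
    if not m.any():
        return
    out.append(Fixation(onset=onset, offset=offset,
                        x_px=float(track.x_px[m].mean()),
                        y_px=float(track.y_px[m].mean())))


def assign_object(fix: Fixation, track: GazeTrack, objects: pd.DataFrame,
                  area: str = "V4",
                  config: AnalysisConfig = DEFAULT_CONFIG) -> Fixation:
    """Label a fixation with the object inside the receptive-field aperture.

    For every valid gaze sample in the fixation, objects whose track point
    lies within a circular aperture (diameter = the area's RF size in
    degrees) centred on the crosshair are candidates; a label is assigned if
    one object kind wins the majority (> 50%) of samples, with ties inside a
    sample resolved by precedence partner > reward > button > floor.
    """
    radius_deg = config.rf_diameter_deg[area] / 2.0
    m = (track.t >= fix.onset) & (track.t < fix.offset) & track.valid.astype(bool)
    times = track.t[m]
    if times.size == 0:
        return fix
    votes: dict[str, int] = {}
    obj_t = objects["t"].to_numpy()
    for t, gx, gy in zip(times, track.x_px[m], track.y_px[m]):
        frame = objects.iloc[np.flatnonzero(obj_t == t)]
        hit_kinds = set()
        for r in frame.itertuples():
            kind = OBJECT_KIND.get(str(r.object))
            if kind is None:
                continue
            if px_to_deg(r.x_px - gx, r.y_px - gy, config) <= radius_deg:
                hit_kinds.add(kind)
        if hit_kinds:
            best = min(hit_kinds, key=KIND_PRECEDENCE.index)
            votes[best] = votes.get(best, 0) + 1
    if not votes:
        return fix
    kind, n = max(votes.items(), key=lambda kv: (kv[1], -KIND_PRECEDENCE.index(kv[0])))
    if n * 2 <= times.size:   # needs a strict majority of fixation samples
        return fix
    return Fixation(fix.onset, fix.offset, fix.x_px, fix.y_px, kind=kind)


def extract_fixation_events(bundle: SessionBundle, area: str = "V4",
                            threshold: float | None = None) -> list[EventRecord]:
    """Full per-session pipeline: speed -> threshold -> fixations -> labels."""
    cfg = bundle.config
    if bundle.gaze is None:
        raise ValueError("bundle has no gaze track")
    if threshold is None:
        sp = eye_speed(bundle.gaze, cfg)
        threshold = find_speed_threshold(sp.speed.to_numpy(), cfg)
    fixations = detect_fixations(bundle.gaze, threshold, cfg)
    events = []
    for f in fixations:
        if bundle.objects is not None:
            f = assign_object(f, bundle.gaze, bundle.objects, area, cfg)
        if f.kind is None:
            continue
        tr = bundle.trial_of(f.onset)
        events.append(EventRecord(f.kind, f.onset, f.offset,
                                  tr.trial_id if tr is not None else -1))
    return events


def fixation_rates(events: list[EventRecord], bundle: SessionBundle,
                   pre_coop_only: bool = True) -> pd.DataFrame:
    """Fixations per second per object kind, trial window vs intertrial.

    The trial window is the pre-cooperation epoch [t_start, t_coop) by
    default; the intertrial window is [t_end, intertrial_end).
    """
    trial_time = 0.0
    iti_time = 0.0
    for tr in bundle.trials:
        stop = tr.t_coop if (pre_coop_only and tr.t_coop is not None) else tr.t_end
        trial_time += (stop - tr.t_start) / 1000.0
        iti_time += (tr.intertrial_end - tr.t_end) / 1000.0
    counts: dict[tuple[str, str], int] = {}
    for ev in events:
        tr = next((t for t in bundle.trials
                   if t.t_start <= ev.onset < t.intertrial_end), None)
        if tr is None:
            continue
        stop = tr.t_coop if (pre_coop_only and tr.t_coop is not None) else tr.t_end
        if ev.onset < stop:
            window = "trial"
        elif ev.onset >= tr.t_end:
            window = "intertrial"
        else:
            continue   # between cooperation onset and trial end: unused
        counts[(ev.kind, window)] = counts.get((ev.kind, window), 0) + 1
    rows = []
    kinds = sorted({k for k, _ in counts})
    for kind in kinds:
        for window, total in (("trial", trial_time), ("intertrial", iti_time)):
            n = counts.get((kind, window), 0)
            rows.append({"object": kind, "window": window, "n": n,
                         "rate_hz": n / total if total > 0 else float("nan")})
    return pd.DataFrame(rows)


def compare_fixation_rates(per_session: list[pd.DataFrame],
                           kind: str) -> dict[str, float]:
    """Paired trial-vs-intertrial comparison of one object's rate across sessions."""
    trial_rates, iti_rates = [], []
    for df in per_session:
        sub = df[df.object == kind]
        tr = sub[sub.window == "trial"].rate_hz
        it = sub[sub.window == "intertrial"].rate_hz
        if len(tr) and len(it):
            trial_rates.append(float(tr.iloc[0]))
            iti_rates.append(float(it.iloc[0]))
    if len(trial_rates) < 2:
        return {"p": float("nan"), "n_sessions": len(trial_rates)}
    return {"p": wilcoxon_signed_rank(trial_rates, iti_rates),
            "n_sessions": len(trial_rates),
            "mean_trial": float(np.mean(trial_rates)),
            "mean_intertrial": float(np.mean(iti_rates))}
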