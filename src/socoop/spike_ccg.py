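"""Normalized, shuffle-corrected spike-train cross-correlograms.

For a pair of units (j, k) and a set of M equal-length event-aligned
segments of their 1 ms binary spike trains, the trial-averaged raw
correlogram is

    C_jk(tau) = (1/M) sum_i sum_t x_j^i(t) x_k^i(t + tau).

Event-locked (stimulus-induced) correlation is removed by subtracting the
all-way shuffle predictor, computed efficiently as the cross-correlation
of the two units' PSTHs.  The corrected correlogram is divided by the
triangle function Theta(tau) = T - |tau| (the overlap of finite segments,
in seconds) and by the geometric mean of the two mean firing rates, giving
a CCG in coincidences per spike whose peak is insensitive to overall rate.
A pair is significantly coordinated when the peak inside the pairing's
physiological lag window (within-area 0-6 ms, inter-areal 15-60 ms)
exceeds 4.5 times the SD of the corrected CCG in tail bands beyond the
window (starting 60 ms out, or 25 ms for fixation events).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bundle import SessionBundle, FIXATION_KINDS, CHOICE_KINDS
from .config import AnalysisConfig, DEFAULT_CONFIG
from .stats import learning_trend


@dataclass
class SpikeSegmentSet:
    """M event-aligned binary 1 ms spike-train segments for a unit pair."""
    x_j: np.ndarray   # M x T binary
    x_k: np.ndarray
    event_kind: str | None = None

    def __post_init__(self) -> None:
        self.x_j = np.asarray(self.x_j)
        self.x_k = np.asarray(self.x_k)
        if self.x_j.shape != self.x_k.shape or self.x_j.ndim != 2:
            raise ValueError("segments must be equal-shape M x T arrays")

    @property
    def m(self) -> int:
        return self.x_j.shape[0]

    @property
    def t(self) -> int:
        return self.x_j.shape[1]


def segments_from_trains(times_j: np.ndarray, times_k: np.ndarray,
                         onsets: np.ndarray, window_ms: tuple[float, float],
                         event_kind: str | None = None) -> SpikeSegmentSet:
    """Bin two spike-time trains into aligned 1 ms segments around events."""
    lo, hi = window_ms
    t_len = int(round(hi - lo))
    edges = np.arange(t_len + 1)
    xs = []
    for times in (times_j, times_k):
        mat = np.zeros((len(onsets), t_len), dtype=np.int8)
        for i, t0 in enumerate(np.asarray(onsets, dtype=float)):
            rel = times - (t0 + lo)
            sel = rel[(rel >= 0) & (rel < t_len)]
            mat[i] = np.minimum(np.histogram(sel, bins=edges)[0], 1)
        xs.append(mat)
    return SpikeSegmentSet(xs[0], xs[1], event_kind=event_kind)


def raw_ccg(segments: SpikeSegmentSet, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged raw correlogram C_jk(tau) for |tau| <= max_lag.

    Returns (lags, values); values are average coincidence counts per
    segment at each lag, with positive tau meaning unit k spikes after
    unit j.
    """
    m, t = segments.m, segments.t
    if max_lag >= t:
        raise ValueError("max_lag must be smaller than the segment length")
    acc = np.zeros(2 * t - 1)
    for xj, xk in zip(segments.x_j.astype(float), segments.x_k.astype(float)):
        # np.correlate(xk, xj)[i] = sum_t xj(t) xk(t + i - (T-1))
        acc += np.correlate(xk, xj, mode="full")
    acc /= m
    centre = t - 1
    lags = np.arange(-max_lag, max_lag + 1)
    return lags, acc[centre - max_lag:centre + max_lag + 1]


def shuffle_predictor(segments: SpikeSegmentSet, max_lag: int) -> np.ndarray:
    """All-way shuffle predictor via PSTH cross-correlation.

    Expected per-trial coincidence count at each lag if trials were
    independent: the cross-correlation of the two trial-averaged PSTHs.
    """
    psth_j = segments.x_j.mean(axis=0)
    psth_k = segments.x_k.mean(axis=0)
    full = np.correlate(psth_k, psth_j, mode="full")
    centre = segments.t - 1
    return full[centre - max_lag:centre + max_lag + 1]


@dataclass
class NeuralCcg:
    lags: np.ndarray          # ms
    raw: np.ndarray           # coincidences per trial
    predictor: np.ndarray
    corrected: np.ndarray     # coincidences per spike, shuffle-corrected
    rate_j: float             # Hz over the analyzed segments
    rate_k: float
    event_kind: str | None = None


def normalized_ccg(segments: SpikeSegmentSet,
                   max_lag: int | None = None,
                   config: AnalysisConfig = DEFAULT_CONFIG) -> NeuralCcg:
    """Shuffle-corrected, triangle- and rate-normalized CCG.

    The raw correlogram minus the shuffle predictor is divided by
    Theta(tau) = (T - |tau|) seconds and by sqrt(rate_j * rate_k); silent
    units make the normalization undefined and raise.
    """
    if max_lag is None:
        max_lag = min(config.ccg_max_lag_ms, segments.t - 1)
    dur_s = segments.t / 1000.0
    rate_j = segments.x_j.sum() / segments.m / dur_s
    rate_k = segments.x_k.sum() / segments.m / dur_s
    if rate_j == 0 or rate_k == 0:
        raise ValueError("silent unit: geometric-mean normalization undefined")
    lags, raw = raw_ccg(segments, max_lag)
    pred = shuffle_predictor(segments, max_lag)
    theta_s = (segments.t - np.abs(lags)) / 1000.0
    corrected = (raw - pred) / (theta_s * np.sqrt(rate_j * rate_k))
    return NeuralCcg(lags=lags, raw=raw, predictor=pred, corrected=corrected,
                     rate_j=rate_j, rate_k=rate_k,
                     event_kind=segments.event_kind)


@dataclass(frozen=True)
class CcgVerdict:
    peak: float
    peak_lag_ms: int
    noise_sd: float
    significant: bool
    pairing: str


def ccg_significance(ccg: NeuralCcg, pairing: str,
                     is_fixation: bool | None = None,
                     config: AnalysisConfig = DEFAULT_CONFIG) -> CcgVerdict:
    """4.5-SD peak test inside the pairing's lag window.

    ``pairing`` is "within" (peak sought at |tau| in 0-6 ms) or "inter"
    (15-60 ms).  Noise SD comes from the corrected CCG in symmetric tail
    bands starting 60 ms beyond the window edge (25 ms for fixation
    events); the configured max lag must reach the tail band.
    """
    if is_fixation is None:
        is_fixation = ccg.event_kind in FIXATION_KINDS
    if pairing == "within":
        lo, hi = config.within_area_lag_ms
    elif pairing == "inter":
        lo, hi = config.inter_area_lag_ms
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    gap = (config.ccg_tail_gap_fixation_ms if is_fixation
           else config.ccg_tail_gap_ms)
    tail_start = hi + gap
    max_lag = int(np.max(ccg.lags))
    if tail_start >= max_lag:
        raise ValueError(
            f"tail band starts at {tail_start} ms but max lag is {max_lag} ms; "
            "increase ccg_max_lag_ms")
    abs_lag = np.abs(ccg.lags)
    in_window = (abs_lag >= lo) & (abs_lag <= hi)
    in_tail = abs_lag >= tail_start
    vals = ccg.corrected[in_window]
    wlags = ccg.lags[in_window]
    # deterministic peak: max value, ties to smallest |lag| then positive
    best = sorted(range(len(vals)),
                  key=lambda i: (-vals[i], abs(int(wlags[i])), -np.sign(wlags[i])))[0]
    peak = float(vals[best])
    noise_sd = float(np.std(ccg.corrected[in_tail]))
    significant = noise_sd > 0 and peak > config.ccg_sd_threshold * noise_sd
    return CcgVerdict(peak=peak, peak_lag_ms=int(wlags[best]),
                      noise_sd=noise_sd, significant=significant,
                      pairing=pairing)


def _pairing(area_j: str, area_k: str) -> str:
    return "within" if area_j == area_k else "inter"


@dataclass
class CoordinationSummary:
    event_kind: str
    area_pairing: str        # "V4-V4", "dlPFC-dlPFC", "V4-dlPFC"
    mean_coordination: float  # mean of significant pairs' peaks (NaN if none)
    n_significant: int
    n_pairs: int
    peak_lags_ms: list[int]   # significant pairs' peak lags (lead-lag histogram)


def event_segment_window(kind: str, area_j: str, area_k: str,
                         config: AnalysisConfig = DEFAULT_CONFIG
                         ) -> tuple[float, float]:
    """Segment window relative to event onset used for pair correlograms.

    Choice and random events use the 800 ms before onset; fixations use the
    200 ms after onset shifted by the visual delay (80 ms for inter-areal
    pairs; the shared area's delay within an area).
    """
    if kind in CHOICE_KINDS or kind == "random":
        return (-float(config.ccg_segment_pre_choice_ms), 0.0)
    if area_j == area_k:
        delay = config.visual_delay_ms[area_j]
    else:
        delay = config.visual_delay_ms["interareal_fixation"]
    return (float(delay), float(delay + config.ccg_segment_post_fixation_ms))


def session_coordination(bundle: SessionBundle,
                         event_kinds: tuple[str, ...] = ("view_reward",
                                                         "view_partner",
                                                         "self_push",
                                                         "partner_push"),
                         max_pairs_per_grouping: int | None = None
                         ) -> list[CoordinationSummary]:
    """Mean coordination per event kind and area pairing for one session.

    V4-dlPFC peak lags follow the convention positive = V4 leads (the V4
    unit is unit j).  Pairs with a silent unit are skipped.
    """
    cfg = bundle.config
    summaries = []
    areas = {u.unit_id: u.area for u in bundle.units}
    unit_ids = [u.unit_id for u in bundle.units]
    pairings = {"V4-V4": [], "dlPFC-dlPFC": [], "V4-dlPFC": []}
    for i, uj in enumerate(unit_ids):
        for uk in unit_ids[i + 1:]:
            aj, ak = areas[uj], areas[uk]
            if aj == ak:
                pairings[f"{aj}-{ak}"].append((uj, uk))
            else:
                v4 = uj if aj == "V4" else uk
                pf = uk if aj == "V4" else uj
                pairings["V4-dlPFC"].append((v4, pf))
    for kind in event_kinds:
        onsets = np.array([e.onset for e in bundle.events_of(kind)], dtype=float)
        if onsets.size == 0:
            continue
        for name, pairs in pairings.items():
            if not pairs:
                continue
            if max_pairs_per_grouping is not None:
                pairs = pairs[:max_pairs_per_grouping]
            peaks, lags_sig = [], []
            n_done = 0
            for uj, uk in pairs:
                aj, ak = areas[uj], areas[uk]
                window = event_segment_window(kind, aj, ak, cfg)
                seg = segments_from_trains(bundle.spike_train(uj).times,
                                           bundle.spike_train(uk).times,
                                           onsets, window, event_kind=kind)
                try:
                    ccg = normalized_ccg(seg, config=cfg)
                except ValueError:
                    continue
                verdict = ccg_significance(ccg, _pairing(aj, ak), config=cfg)
                n_done += 1
                if verdict.significant:
                    peaks.append(verdict.peak)
                    lags_sig.append(verdict.peak_lag_ms)
            summaries.append(CoordinationSummary(
                event_kind=kind, area_pairing=name,
                mean_coordination=float(np.mean(peaks)) if peaks else float("nan"),
                n_significant=len(peaks), n_pairs=n_done,
                peak_lags_ms=lags_sig))
    return summaries


def coordination_trend(per_session: list[list[CoordinationSummary]],
                       event_kind: str, area_pairing: str):
    """Learning trend of mean coordination for one event/pairing across sessions."""
    vals = []
    for summaries in per_session:
        v = [s.mean_coordination for s in summaries
             if s.event_kind == event_kind and s.area_pairing == area_pairing]
        vals.append(v[0] if v and np.isfinite(v[0]) else np.nan)
    arr = np.asarray(vals, dtype=float)
    ok = np.isfinite(arr)
    if ok.sum() < 3:
        raise ValueError("need >= 3 sessions with significant pairs")
    return learning_trend(arr[ok], sessions=np.flatnonzero(ok) + 1)
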