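"""Event-locked firing-rate analysis: PETHs, response-vs-baseline tests,
cell-class assignment, and d' discriminability.

For each unit and each of the four salient events, per-observation firing
rates in the event's response window are compared against matched-duration
baseline rates drawn from the intertrial period 4.5 s before each trial
start, using a paired two-sided Wilcoxon signed-rank test with
Benjamini-Hochberg FDR correction at alpha = 0.01.  Fixation responses are
counted 130 ms after fixation onset shifted by the area's visual delay
(60 ms V4, 80 ms dlPFC); choice responses use the 1000 ms before push
onset.  Cells are classed as choice-only, fixation-only, mixed (at least
one of each) or other (none).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bundle import (EventRecord, SessionBundle, SpikeTrain, UnitMeta,
                     CHOICE_KINDS, FIXATION_KINDS)
from .config import AnalysisConfig, DEFAULT_CONFIG
from .stats import fdr_correct, wilcoxon_signed_rank

RESPONSE_EVENTS = ("view_reward", "view_partner", "self_push", "partner_push")


def peth(train: SpikeTrain, onsets: np.ndarray, window_ms: tuple[float, float],
         bin_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Peri-event time histogram in Hz.

    Returns ``(bin_left_edges_ms, rate_hz)``; counts are averaged over
    events and divided by the bin width, so ``sum(rate) * bin_s`` equals
    the mean spike count per event in the window.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("peth requires at least one event")
    lo, hi = window_ms
    edges = np.arange(lo, hi + 0.5 * bin_ms, bin_ms)
    counts = np.zeros(len(edges) - 1)
    for t0 in onsets:
        rel = train.times - t0
        sel = rel[(rel >= lo) & (rel < hi)]
        counts += np.histogram(sel, bins=edges)[0]
    rate = counts / onsets.size / (bin_ms / 1000.0)
    return edges[:-1], rate


def response_window(kind: str, area: str,
                    config: AnalysisConfig = DEFAULT_CONFIG
                    ) -> tuple[float, float]:
    """(start, stop) ms relative to event onset for the analysis window."""
    if kind in FIXATION_KINDS:
        delay = config.visual_delay_ms[area]
        return (delay, delay + config.fixation_response_ms)
    if kind in CHOICE_KINDS:
        return (-config.push_response_ms, 0.0)
    raise ValueError(f"no response window for event kind {kind!r}")


def _isolated(onsets: np.ndarray, min_gap_ms: float = 1000.0) -> np.ndarray:
    """Keep only events separated from their neighbours by > min_gap_ms."""
    if onsets.size <= 1:
        return onsets
    o = np.sort(onsets)
    keep = np.ones(o.size, dtype=bool)
    keep[1:] &= np.diff(o) > min_gap_ms
    keep[:-1] &= np.diff(o) > min_gap_ms
    return o[keep]


def observation_rates(train: SpikeTrain, onsets: np.ndarray,
                      window: tuple[float, float]) -> np.ndarray:
    """Firing rate (Hz) in ``window`` relative to each event onset."""
    lo, hi = window
    dur_s = (hi - lo) / 1000.0
    t0 = np.asarray(onsets, dtype=float)
    counts = (np.searchsorted(train.times, t0 + hi, side="left")
              - np.searchsorted(train.times, t0 + lo, side="left"))
    return counts / dur_s


def baseline_onsets(bundle: SessionBundle, duration_ms: float) -> np.ndarray:
    """One matched-duration baseline epoch per trial, ending 4.5 s pre-start.

    The baseline segment is drawn from the end of the window that sits
    ``baseline_offset_ms`` before each trial start (intertrial time).
    """
    off = bundle.config.baseline_offset_ms
    return np.array([tr.t_start - off for tr in bundle.trials
                     if tr.t_start - off - duration_ms >= 0], dtype=float)


@dataclass
class EventTest:
    kind: str
    n_obs: int
    mean_rate: float
    baseline_rate: float
    p: float
    significant: bool = False


@dataclass
class CellResponseProfile:
    unit: UnitMeta
    tests: dict[str, EventTest]

    @property
    def cell_class(self) -> str:
        sig_choice = any(t.significant for k, t in self.tests.items()
                         if k in CHOICE_KINDS)
        sig_fix = any(t.significant for k, t in self.tests.items()
                      if k in FIXATION_KINDS)
        if sig_choice and sig_fix:
            return "mixed"
        if sig_choice:
            return "choice_only"
        if sig_fix:
            return "fixation_only"
        return "other"


def response_significance(bundle: SessionBundle, unit: UnitMeta, kind: str,
                          min_events: int = 5) -> EventTest:
    """Paired response-vs-baseline signed-rank test for one unit and event.

    Choice events must be isolated by more than 1 s from each other; each
    observation's response rate is paired with a matched-duration baseline
    rate from its trial's pre-start intertrial window.  Events in trials
    with no usable baseline, or occurring after the tray started moving
    (beyond cooperation onset), are dropped.
    """
    cfg = bundle.config
    train = bundle.spike_train(unit.unit_id)
    window = response_window(kind, unit.area, cfg)
    onsets = np.array([e.onset for e in bundle.events_of(kind)
                       if _pre_coop(bundle, e)], dtype=float)
    if kind in CHOICE_KINDS:
        onsets = _isolated(onsets, 1000.0)
    dur = window[1] - window[0]
    base = baseline_onsets(bundle, dur)
    # pair each observation with its trial's baseline epoch
    paired_resp, paired_base = [], []
    base_by_trial = {}
    for tr, b in zip([t for t in bundle.trials
                      if t.t_start - cfg.baseline_offset_ms - dur >= 0], base):
        base_by_trial[tr.trial_id] = b
    for t0 in onsets:
        tr = bundle.trial_of(int(t0))
        if tr is None or tr.trial_id not in base_by_trial:
            continue
        paired_resp.append(t0)
        paired_base.append(base_by_trial[tr.trial_id])
    if len(paired_resp) < min_events:
        return EventTest(kind, len(paired_resp), float("nan"), float("nan"),
                         float("nan"))
    resp = observation_rates(train, np.asarray(paired_resp), window)
    bl = observation_rates(train, np.asarray(paired_base), (-dur, 0.0))
    p = wilcoxon_signed_rank(resp, bl)
    return EventTest(kind, len(resp), float(resp.mean()), float(bl.mean()), p)


def _pre_coop(bundle: SessionBundle, ev: EventRecord) -> bool:
    """True if the event avoids the tray-movement epoch [t_coop, t_end)."""
    tr = bundle.trial_of(ev.onset)
    if tr is None:
        return False
    if tr.t_coop is None:
        return ev.onset < tr.t_end
    return ev.onset < tr.t_coop or ev.onset >= tr.t_end


def profile_cells(bundle: SessionBundle,
                  events: tuple[str, ...] = RESPONSE_EVENTS,
                  min_events: int = 5,
                  fdr_family: str = "per_unit") -> list[CellResponseProfile]:
    """Per-unit event tests with FDR correction.

    ``fdr_family`` selects the correction family: ``per_unit`` (default)
    corrects each unit's event tests together; ``global`` pools all
    unit x event p-values into one family.
    """
    alpha = bundle.config.fdr_alpha
    profiles = []
    for unit in bundle.units:
        tests = {k: response_significance(bundle, unit, k, min_events)
                 for k in events}
        if fdr_family == "per_unit":
            testable = [k for k in events if np.isfinite(tests[k].p)]
            if testable:
                rej = fdr_correct([tests[k].p for k in testable], alpha=alpha)
                for k, r in zip(testable, rej):
                    tests[k].significant = bool(r)
        profiles.append(CellResponseProfile(unit=unit, tests=tests))
    if fdr_family == "global":
        flat = [(p, k) for p in profiles for k, t in p.tests.items()
                if np.isfinite(t.p)]
        if flat:
            rej = fdr_correct([p.tests[k].p for p, k in flat], alpha=alpha)
            for (p, k), r in zip(flat, rej):
                p.tests[k].significant = bool(r)
    elif fdr_family != "per_unit":
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    return profiles


def classify_cells(profiles: list[CellResponseProfile]) -> dict[str, dict[str, float]]:
    """Percentage of units per class (choice_only/fixation_only/mixed/other), per area."""
    out: dict[str, dict[str, float]] = {}
    areas = sorted({p.unit.area for p in profiles})
    for area in areas:
        ps = [p for p in profiles if p.unit.area == area]
        classes = [p.cell_class for p in ps]
        out[area] = {c: 100.0 * classes.count(c) / len(classes)
                     for c in ("choice_only", "fixation_only", "mixed", "other")}
    return out


def d_prime(u_a: float, u_b: float, sigma_a: float, sigma_b: float,
            convention: str = "printed") -> float:
    """Discriminability index between responses to two stimuli.

    ``printed`` uses ``(u_a - u_b) / (0.5 * sqrt(sigma_a^2 + sigma_b^2))``;
    ``rms`` uses the common root-mean-square-sigma denominator
    ``sqrt((sigma_a^2 + sigma_b^2) / 2)``.
    """
    s2 = sigma_a ** 2 + sigma_b ** 2
    if s2 == 0:
        raise ZeroDivisionError("both response variances are zero")
    if convention == "printed":
        denom = 0.5 * np.sqrt(s2)
    elif convention == "rms":
        denom = np.sqrt(s2 / 2.0)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float((u_a - u_b) / denom)
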