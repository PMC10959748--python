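"""Assembly of complete synthetic session bundles for end-to-end runs.

Builds sessions whose timeline mirrors the task: a trial starts at pellet
dispense, the pre-cooperation epoch carries fixations on the reward system
and partner plus isolated self/partner pushes, cooperation onset is the
first bin with both monkeys pushing (a forced joint hold), trays then
travel, and an intertrial interval long enough for the 4.5 s pre-start
baseline follows.  Spike trains come from the event-locked Poisson
generator, so response, decoding, and spike-coordination stages all see
the statistical structure they assume, with the ground truth on the side.
"""

from __future__ import annotations

import numpy as np

from ..bundle import EventRecord, SessionBundle, TrialWindow, UnitMeta
from ..config import AnalysisConfig, DEFAULT_CONFIG
from .params import GroundTruth, SpikeSimParams
from .spikes import simulate_spikes

TRIAL_PRE_COOP_MS = 12_000
TRAY_TRAVEL_MS = 2_000
ITI_MS = 8_000
PUSH_HOLD_MS = 300
FIX_DUR_MS = 150


def default_units(n_v4: int = 6, n_pfc: int = 6) -> list[UnitMeta]:
    units = []
    for i in range(n_v4):
        units.append(UnitMeta(f"v4_{i:02d}", electrode=i + 1, area="V4",
                              unit_class="single"))
    for i in range(n_pfc):
        units.append(UnitMeta(f"pfc_{i:02d}", electrode=33 + i, area="dlPFC",
                              unit_class="single"))
    return units


def tuned_gains(units: list[UnitMeta], rng: np.random.Generator,
                gain: float = 2.0,
                informative: dict[str, float] | None = None
                ) -> dict[str, dict[str, float]]:
    """Event-gain map giving each unit a preference among the four events.

    ``informative`` optionally maps unit_id to a multiplier on the gain
    contrast (0 = untuned), used to concentrate or distribute the decodable
    signal across the population.
    """
    gains: dict[str, dict[str, float]] = {}
    for k, u in enumerate(units):
        w = 1.0 if informative is None else informative.get(u.unit_id, 0.0)
        g = 1.0 + (gain - 1.0) * w
        if k % 2 == 0:
            gains[u.unit_id] = {"view_reward": g, "self_push": g}
        else:
            gains[u.unit_id] = {"view_partner": g, "partner_push": g}
    return gains


def build_trial_events(trial: TrialWindow, rng: np.random.Generator,
                       n_fix_per_kind: int = 4,
                       fixation_kinds: tuple[str, ...] = ("view_reward",
                                                          "view_partner")
                       ) -> list[EventRecord]:
    """Fixations and isolated pushes inside one trial's pre-cooperation epoch."""
    events = []
    t0, t1 = trial.t_start + 500, trial.t_coop - 1500
    # pushes: alternating, >= 2 s apart
    push_times = np.arange(t0 + 4000, t1, 2500)[:4]
    for i, pt in enumerate(push_times):
        kind = "self_push" if i % 2 == 0 else "partner_push"
        events.append(EventRecord(kind, int(pt), int(pt + PUSH_HOLD_MS),
                                  trial.trial_id))
    # fixations: jittered grid avoiding push onsets by >= 300 ms
    n_fix = n_fix_per_kind * len(fixation_kinds)
    slots = np.linspace(t0, t1 - FIX_DUR_MS, n_fix) + rng.uniform(0, 120, n_fix)
    kinds = list(fixation_kinds) * n_fix_per_kind
    rng.shuffle(kinds)
    for slot, kind in zip(slots, kinds):
        onset = int(slot)
        if any(abs(onset - pt) < 400 for pt in push_times):
            onset += 450
        if onset + FIX_DUR_MS >= trial.t_coop:
            continue
        events.append(EventRecord(kind, onset, onset + FIX_DUR_MS,
                                  trial.trial_id))
    return sorted(events, key=lambda e: e.onset)


def simulate_neural_session(session_index: int, rng: np.random.Generator,
                            n_trials: int = 12,
                            units: list[UnitMeta] | None = None,
                            spike_params: SpikeSimParams | None = None,
                            n_fix_per_kind: int = 4,
                            fixation_kinds: tuple[str, ...] = ("view_reward",
                                                               "view_partner"),
                            config: AnalysisConfig = DEFAULT_CONFIG
                            ) -> tuple[SessionBundle, GroundTruth]:
    """One full synthetic session: trials, events, pushes, and spike trains."""
    units = units if units is not None else default_units()
    if spike_params is None:
        spike_params = SpikeSimParams(event_gains=tuned_gains(units, rng))
    trials: list[TrialWindow] = []
    events: list[EventRecord] = []
    t = ITI_MS
    for trial_id in range(1, n_trials + 1):
        t_start = t
        t_coop = t_start + TRIAL_PRE_COOP_MS
        t_end = t_coop + TRAY_TRAVEL_MS
        tr = TrialWindow(trial_id, t_start, t_coop, t_end, t_end + ITI_MS)
        trials.append(tr)
        events.extend(build_trial_events(tr, rng, n_fix_per_kind,
                                         fixation_kinds))
        t = t_end + ITI_MS
    total_ms = t
    bw = config.push_bin_ms
    pushes = {"self": np.zeros(total_ms // bw, dtype=np.int8),
              "partner": np.zeros(total_ms // bw, dtype=np.int8)}
    for ev in events:
        if ev.kind in ("self_push", "partner_push"):
            who = "self" if ev.kind == "self_push" else "partner"
            pushes[who][ev.onset // bw:-(-ev.offset // bw)] = 1
    for tr in trials:
        for who in pushes:   # joint hold defines cooperation onset
            pushes[who][tr.t_coop // bw:tr.t_end // bw] = 1
    spikes = simulate_spikes(spike_params, units, events, total_ms, rng,
                             config)
    bundle = SessionBundle(session_index=session_index, pair_id="sim_pair",
                           trials=trials, pushes=pushes, gaze=None,
                           objects=None, events=events, spikes=spikes,
                           units=units, config=config).validate()
    truth = GroundTruth(
        event_gains=spike_params.event_gains,
        coupled_pairs=[{"unit_i": c.unit_i, "unit_j": c.unit_j,
                        "coincidence_prob": c.coincidence_prob,
                        "lag_ms": c.lag_ms,
                        "event_kinds": list(c.event_kinds or [])}
                       for c in spike_params.coupled_pairs])
    return bundle, truth


def simulate_decode_observations(n_per_class: int, n_units: int,
                                 separation: float,
                                 rng: np.random.Generator,
                                 informative: np.ndarray | None = None
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Population rate vectors for a two-class decoding problem.

    Class means differ by ``separation`` (in units of the unit-level noise
    SD) on informative units; ``informative`` is a per-unit multiplier
    (default all ones).  ``separation = 0`` gives label-independent
    features.  Rates are baseline 10 Hz plus Gaussian variability.
    """
    w = np.ones(n_units) if informative is None else np.asarray(informative,
                                                                dtype=float)
    if w.size != n_units:
        raise ValueError("informative mask length must equal n_units")
    y = np.repeat([0, 1], n_per_class)
    offsets = np.outer(y - 0.5, separation * w)
    X = 10.0 + offsets + rng.normal(0.0, 1.0, (2 * n_per_class, n_units))
    return X, y
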