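"""Per-channel waveform clusters with planned stable and replaced units.

A unit's waveform template is a biphasic difference of Gaussians with
randomly drawn amplitude, width, and trough position.  Stable units keep
their template across sessions (plus i.i.d. noise per sampled waveform);
a replaced unit switches to a freshly drawn, well-separated template at
its replacement session.
"""

from __future__ import annotations

import numpy as np

from .params import WaveformPlan


def _template(rng: np.random.Generator, n_samples: int) -> np.ndarray:
    t = np.arange(n_samples, dtype=float)
    trough = rng.uniform(0.3, 0.45) * n_samples
    peak = trough + rng.uniform(0.15, 0.3) * n_samples
    w1 = rng.uniform(0.04, 0.08) * n_samples
    w2 = rng.uniform(0.08, 0.16) * n_samples
    a1 = rng.uniform(0.8, 1.2)
    a2 = rng.uniform(0.3, 0.6)
    return (-a1 * np.exp(-0.5 * ((t - trough) / w1) ** 2)
            + a2 * np.exp(-0.5 * ((t - peak) / w2) ** 2))


def simulate_waveforms(plan: WaveformPlan
                       ) -> tuple[dict[tuple[str, int], np.ndarray],
                                  dict[str, tuple[int, str]],
                                  dict[str, bool]]:
    """Waveform matrices per (unit_id, session) plus metadata and truth.

    Returns ``(waveforms, meta, truth)`` where waveforms maps
    ``(unit_id, session)`` to an (n_waveforms x samples) matrix, meta maps
    unit_id to (electrode, area), and truth maps ``"elec:sa->sb"`` to
    whether the unit on that electrode is the same neuron across the pair
    of consecutive sessions.
    """
    rng = np.random.default_rng(plan.seed)
    waveforms: dict[tuple[str, int], np.ndarray] = {}
    meta: dict[str, tuple[int, str]] = {}
    truth: dict[str, bool] = {}
    for elec in range(1, plan.n_electrodes + 1):
        area = "V4" if elec <= plan.n_electrodes // 2 else "dlPFC"
        tmpl = _template(rng, plan.samples_per_waveform)
        swap_at = plan.replaced_at.get(elec)
        for session in range(1, plan.n_sessions + 1):
            if swap_at is not None and session == swap_at:
                old = tmpl
                while True:   # redraw until clearly separated in shape
                    tmpl = _template(rng, plan.samples_per_waveform)
                    if np.linalg.norm(tmpl - old) > 0.5:
                        break
            uid = f"e{elec:02d}"
            meta[uid] = (elec, area)
            noise = rng.normal(0.0, plan.noise_sd,
                               (plan.n_waveforms, plan.samples_per_waveform))
            waveforms[(uid, session)] = tmpl[None, :] + noise
            if session > 1:
                same = not (swap_at is not None and session == swap_at)
                truth[f"{elec}:{session - 1}->{session}"] = same
    return waveforms, meta, truth
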