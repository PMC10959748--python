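"""First-order Markov social-event sequences from a known transition matrix."""

from __future__ import annotations

import numpy as np

from ..markov import STATES


def simulate_event_sequence(matrix: np.ndarray, n_events: int,
                            rng: np.random.Generator,
                            start: str | None = None) -> list[str]:
    """One first-order Markov chain over the four social-event states."""
    p = np.asarray(matrix, dtype=float)
    if p.shape != (4, 4) or not np.allclose(p.sum(axis=1), 1.0):
        raise ValueError("transition matrix must be 4x4 row-stochastic")
    state = (rng.integers(4) if start is None else STATES.index(start))
    seq = [STATES[state]]
    for _ in range(n_events - 1):
        state = rng.choice(4, p=p[state])
        seq.append(STATES[state])
    return seq


def simulate_trial_sequences(matrix: np.ndarray, n_trials: int,
                             events_per_trial: int,
                             rng: np.random.Generator) -> list[list[str]]:
    """Per-trial event sequences drawn from one known matrix."""
    return [simulate_event_sequence(matrix, events_per_trial, rng)
            for _ in range(n_trials)]


def learning_matrix_schedule(n_sessions: int,
                             view_to_push_range: tuple[float, float] = (0.25, 0.6)
                             ) -> list[np.ndarray]:
    """Session-indexed matrices with rising view->push transitions.

    Emulates the learning pattern: transitions from viewing a social cue
    into a push grow across sessions while push->push transitions stay
    flat and low; each row is renormalized.
    """
    mats = []
    for s in range(n_sessions):
        a = np.interp(s, [0, n_sessions - 1], view_to_push_range)
        m = np.array([
            # to: view_reward, view_partner, self_push, partner_push
            [0.10, 0.30, a, 1.0],            # from view_reward
            [0.30, 0.10, a, 1.0],            # from view_partner
            [0.40, 0.40, 0.05, 0.10],        # from self_push (flat, low)
            [0.40, 0.40, 0.10, 0.05],        # from partner_push
        ])
        m[0, 3] = a                           # view -> partner_push also grows
        m[1, 3] = a
        m /= m.sum(axis=1, keepdims=True)
        mats.append(m)
    return mats
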