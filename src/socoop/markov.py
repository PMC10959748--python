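"""First-order Markov transition modelling of social-event sequences.

Within each trial the ordered sequence of the four salient events --
view_reward, view_partner, self_push, partner_push -- is reduced to bigram
counts and maximum-likelihood transition probabilities
``P(a -> b) = count(a -> b) / count(a -> .)``.  Only trials in which all
four events occur are included; per-trial matrices are averaged
element-wise into a session matrix, ignoring rows with no outgoing
transition (reported as missing, not zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bundle import EventRecord, SessionBundle, CHOICE_KINDS

STATES = ("view_reward", "view_partner", "self_push", "partner_push")
_IDX = {s: i for i, s in enumerate(STATES)}


class ExcludedTrialError(ValueError):
    """Trial does not contain all four states and is excluded."""


@dataclass(frozen=True)
class TransitionMatrix:
    probs: np.ndarray    # 4x4; NaN rows where a state has no outgoing transition
    counts: np.ndarray   # 4x4 integer bigram counts
    n_transitions: int

    def p(self, frm: str, to: str) -> float:
        return float(self.probs[_IDX[frm], _IDX[to]])


def estimate_transitions(sequence: list[str],
                         require_all_states: bool = True) -> TransitionMatrix:
    """Maximum-likelihood transition estimates from one event sequence.

    With ``require_all_states`` (the trial-inclusion rule) a sequence
    missing any of the four states raises ``ExcludedTrialError``.
    """
    for s in sequence:
        if s not in _IDX:
            raise ValueError(f"unknown state {s!r}")
    if require_all_states and set(sequence) != set(STATES):
        raise ExcludedTrialError(
            f"sequence covers {sorted(set(sequence))}, needs all four states")
    counts = np.zeros((4, 4), dtype=int)
    for a, b in zip(sequence, sequence[1:]):
        counts[_IDX[a], _IDX[b]] += 1
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row > 0, counts / np.maximum(row, 1), np.nan)
    return TransitionMatrix(probs=probs, counts=counts,
                            n_transitions=int(counts.sum()))


def trial_event_sequence(bundle: SessionBundle, trial_id: int) -> list[str]:
    """Ordered four-state event sequence for one trial's analysis epoch.

    Events are ordered by onset; simultaneous onsets put pushes before
    fixations (documented tie-break).
    """
    evs = [e for e in bundle.events
           if e.trial_id == trial_id and e.kind in STATES]
    evs.sort(key=lambda e: (e.onset, 0 if e.kind in CHOICE_KINDS else 1))
    return [e.kind for e in evs]


@dataclass
class SessionTransitions:
    mean_probs: np.ndarray      # 4x4, NaN where no included trial had the row
    n_trials_included: int
    n_trials_total: int

    @property
    def inclusion_fraction(self) -> float:
        return (self.n_trials_included / self.n_trials_total
                if self.n_trials_total else float("nan"))

    def p(self, frm: str, to: str) -> float:
        return float(self.mean_probs[_IDX[frm], _IDX[to]])


def session_transition_summary(bundle: SessionBundle) -> SessionTransitions:
    """Element-wise mean of per-trial transition matrices over included trials."""
    mats = []
    total = 0
    for tr in bundle.trials:
        seq = trial_event_sequence(bundle, tr.trial_id)
        if not seq:
            continue
        total += 1
        try:
            mats.append(estimate_transitions(seq).probs)
        except ExcludedTrialError:
            continue
    if not mats:
        return SessionTransitions(np.full((4, 4), np.nan), 0, total)
    stack = np.stack(mats)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows allowed
        mean = np.nanmean(stack, axis=0)
    return SessionTransitions(mean_probs=mean, n_trials_included=len(mats),
                              n_trials_total=total)
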