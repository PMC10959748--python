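"""Dyadic push coordination: cross-correlograms, conditional cooperation
probabilities, and response delays.

Each monkey's choice to cooperate is a binary series in 100 ms bins (1 =
pushing).  Per-trial series are cross-correlated with coefficient
normalization (each series' zero-lag autocorrelation equals 1), averaged
lag-wise into a session CCG, and summarized by the peak coincident-push
value and its lag.  Positive lag means the self-monkey leads.  A shuffle
control permutes each monkey's push bins within every trial, destroying
coincidence while preserving push counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bundle import SessionBundle, TrialWindow


class DegenerateSeriesError(ValueError):
    """Raised when an all-zero series makes coefficient normalization undefined."""


@dataclass(frozen=True)
class PushCcg:
    lags: np.ndarray     # bin lags, -(L-1)..(L-1); positive = self leads
    values: np.ndarray
    kind: str            # "actual" | "shuffled"

    @property
    def peak(self) -> float:
        return float(np.max(self.values))

    @property
    def peak_lag(self) -> int:
        return int(self.lags[_peak_index(self.values, self.lags)])


def _peak_index(values: np.ndarray, lags: np.ndarray) -> int:
    """Index of the maximum; ties broken by smallest |lag|, then positive lag."""
    m = np.max(values)
    cand = np.flatnonzero(values >= m - 1e-12)
    order = sorted(cand, key=lambda i: (abs(int(lags[i])), -np.sign(lags[i])))
    return int(order[0])


def push_ccg(self_series: np.ndarray, partner_series: np.ndarray,
             kind: str = "actual") -> PushCcg:
    """Coefficient-normalized cross-correlogram of two equal-length push series.

    ``ccg(tau) = sum_t self(t) * partner(t + tau)`` scaled by the geometric
    mean of the two zero-lag autocorrelations, so identical series give a
    peak of exactly 1 at lag 0.
    """
    a = np.asarray(self_series, dtype=float)
    b = np.asarray(partner_series, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("push series must be equal-length 1-D arrays")
    norm = np.sqrt(np.dot(a, a) * np.dot(b, b))
    if norm == 0:
        raise DegenerateSeriesError("all-zero push series")
    # np.correlate(b, a, "full")[k] = sum_t a(t) b(t + k - (L-1))
    vals = np.correlate(b, a, mode="full") / norm
    lags = np.arange(-(len(a) - 1), len(a))
    return PushCcg(lags=lags, values=vals, kind=kind)


def trial_push_series(bundle: SessionBundle, trial: TrialWindow,
                      end_at_coop: bool = False) -> dict[str, np.ndarray]:
    """Slice each monkey's session push series to one trial's 100 ms bins.

    By default the series runs to trial end; ``end_at_coop`` restricts it to
    the pre-cooperation epoch ``[t_start, t_coop)``.
    """
    bw = bundle.config.push_bin_ms
    t_stop = trial.t_coop if (end_at_coop and trial.t_coop is not None) else trial.t_end
    b0, b1 = trial.t_start // bw, -(-t_stop // bw)
    out = {}
    for monkey, series in bundle.pushes.items():
        seg = series[b0:b1]
        if len(seg) < b1 - b0:  # pad a truncated tail
            seg = np.pad(seg, (0, (b1 - b0) - len(seg)))
        out[monkey] = seg.astype(float)
    return out


@dataclass
class SessionCoordination:
    mean_ccg: PushCcg
    peak: float
    peak_lag_bins: int
    peak_lag_ms: int
    shuffled_ccg: PushCcg
    shuffled_peak: float
    n_trials_used: int
    skipped_trials: list[int]


def session_push_coordination(bundle: SessionBundle,
                              rng: np.random.Generator | None = None,
                              end_at_coop: bool = False,
                              n_shuffles: int = 1) -> SessionCoordination:
    """Average per-trial push CCGs lag-wise into a session CCG.

    Trials may differ in length; trial CCGs are aligned at lag 0 and
    averaged over the trials defined at each lag.  The shuffle control
    permutes each monkey's bins independently within every trial
    (``n_shuffles`` repetitions averaged).
    """
    rng = rng or np.random.default_rng(bundle.config.rng_seed)
    actual, shuffled, skipped = [], [], []
    for trial in bundle.trials:
        series = trial_push_series(bundle, trial, end_at_coop=end_at_coop)
        try:
            actual.append(push_ccg(series["self"], series["partner"]))
        except DegenerateSeriesError:
            skipped.append(trial.trial_id)
            continue
        shuf_vals = []
        for _ in range(n_shuffles):
            s = rng.permutation(series["self"])
            p = rng.permutation(series["partner"])
            shuf_vals.append(push_ccg(s, p, kind="shuffled"))
        shuffled.append(_average_ccgs(shuf_vals, kind="shuffled"))
    if not actual:
        raise DegenerateSeriesError("no valid trials in session")
    mean_ccg = _average_ccgs(actual, kind="actual")
    mean_shuf = _average_ccgs(shuffled, kind="shuffled")
    i = _peak_index(mean_ccg.values, mean_ccg.lags)
    return SessionCoordination(
        mean_ccg=mean_ccg, peak=float(mean_ccg.values[i]),
        peak_lag_bins=int(mean_ccg.lags[i]),
        peak_lag_ms=int(mean_ccg.lags[i]) * bundle.config.push_bin_ms,
        shuffled_ccg=mean_shuf, shuffled_peak=mean_shuf.peak,
        n_trials_used=len(actual), skipped_trials=skipped)


def _average_ccgs(ccgs: list[PushCcg], kind: str) -> PushCcg:
    max_lag = max(int(c.lags[-1]) for c in ccgs)
    lags = np.arange(-max_lag, max_lag + 1)
    acc = np.zeros(len(lags))
    cnt = np.zeros(len(lags))
    for c in ccgs:
        lo = max_lag - int(c.lags[-1])
        acc[lo:lo + len(c.values)] += c.values
        cnt[lo:lo + len(c.values)] += 1
    with np.errstate(invalid="ignore"):
        vals = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    return PushCcg(lags=lags, values=vals, kind=kind)


def conditional_cooperation(self_series: np.ndarray,
                            partner_series: np.ndarray) -> dict[str, float]:
    """Conditional probabilities of cooperating within one trial.

    ``P(Self|Part) = P(Self and Part) / P(Part)`` and symmetrically for the
    partner, with probabilities estimated as bin fractions.  A monkey that
    never pushed makes the corresponding probability undefined (NaN).
    """
    a = np.asarray(self_series, dtype=float)
    b = np.asarray(partner_series, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must be equal length")
    p_self, p_part = a.mean(), b.mean()
    p_joint = (a * b).mean()
    return {
        "p_self_given_part": p_joint / p_part if p_part > 0 else float("nan"),
        "p_part_given_self": p_joint / p_self if p_self > 0 else float("nan"),
    }


def session_conditional_cooperation(bundle: SessionBundle,
                                    end_at_coop: bool = False) -> dict[str, float]:
    """Trial-averaged conditional cooperation probabilities for a session."""
    per_trial = {"p_self_given_part": [], "p_part_given_self": []}
    for trial in bundle.trials:
        series = trial_push_series(bundle, trial, end_at_coop=end_at_coop)
        probs = conditional_cooperation(series["self"], series["partner"])
        for k, v in probs.items():
            if np.isfinite(v):
                per_trial[k].append(v)
    return {k: float(np.mean(v)) if v else float("nan")
            for k, v in per_trial.items()}


def delay_to_cooperate(bundle: SessionBundle,
                       trial: TrialWindow) -> dict[str, float]:
    """Per-monkey delay (ms) from trial start to the first push bin onset."""
    series = trial_push_series(bundle, trial, end_at_coop=False)
    bw = bundle.config.push_bin_ms
    out = {}
    for monkey, s in series.items():
        nz = np.flatnonzero(s)
        out[monkey] = float(nz[0] * bw) if nz.size else float("nan")
    return out


def session_delays(bundle: SessionBundle) -> dict[str, float]:
    """Session-mean delay to cooperate per monkey (NaN-trials excluded)."""
    vals: dict[str, list[float]] = {m: [] for m in bundle.pushes}
    for trial in bundle.trials:
        for monkey, d in delay_to_cooperate(bundle, trial).items():
            if np.isfinite(d):
                vals[monkey].append(d)
    return {m: float(np.mean(v)) if v else float("nan") for m, v in vals.items()}
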