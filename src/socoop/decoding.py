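"""Linear-SVM population decoding with shuffle correction and weight analysis.

Single-observation population rate vectors (one mean rate per unit in the
event's response window) are classified into two event labels with a
linear-kernel SVM (regularization C = 1, no feature standardization) under
tenfold cross-validation.  Every iteration re-balances the classes by
subsampling the larger one and trains, on the same balanced data, a second
decoder with randomly shuffled labels; means over 100 iterations give the
actual accuracy, the shuffled (chance) accuracy, and their difference, the
shuffle-corrected accuracy.  Per-unit weights are normalized to a unit
Euclidean norm, and the variance/kurtosis/skewness of the absolute
normalized weights index how concentrated the decoded information is
across the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .config import AnalysisConfig, DEFAULT_CONFIG
from .stats import learning_trend, TrendResult, wilcoxon_signed_rank


@dataclass
class DecodeProblem:
    X: np.ndarray            # n_obs x n_units population rates
    y: np.ndarray            # binary labels (any two values)
    name: str = "decode"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be n_obs x n_units aligned with y")
        if len(np.unique(self.y)) != 2:
            raise ValueError("decoding problems are binary")


@dataclass
class DecodeResult:
    mean_accuracy_actual: float      # %
    mean_accuracy_shuffled: float    # %
    train_accuracy: float            # % (overfitting check)
    weights: np.ndarray              # per-unit, from a single balanced refit
    normalized_weights: np.ndarray   # unit Euclidean norm
    n_iterations: int
    n_test_splits: int
    per_iteration_actual: np.ndarray = field(repr=False, default=None)
    per_iteration_shuffled: np.ndarray = field(repr=False, default=None)

    @property
    def shuffle_corrected(self) -> float:
        return self.mean_accuracy_actual - self.mean_accuracy_shuffled


def _balance(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subsample (larger class subsampled)."""
    classes, counts = np.unique(y, return_counts=True)
    n = counts.min()
    idx = []
    for c in classes:
        members = np.flatnonzero(y == c)
        idx.append(rng.choice(members, size=n, replace=False))
    return np.sort(np.concatenate(idx))


def _new_svm() -> SVC:
    # linear kernel, C = 1, no standardization
    return SVC(kernel="linear", C=1.0)


def decode(problem: DecodeProblem, seed: int = 0,
           config: AnalysisConfig = DEFAULT_CONFIG,
           weight_mode: str = "refit") -> DecodeResult:
    """Cross-validated decoding with per-iteration balancing and shuffle null.

    Requires at least ``config.cv_folds`` observations per class after
    balancing (folds must be splittable); accuracies are percentages of
    correctly classified held-out observations.  ``weight_mode`` selects
    whether reported weights come from one model refit on all balanced
    observations (``refit``, default) or from averaging the fold models of
    a final cross-validation pass (``fold_mean``).
    """
    if weight_mode not in ("refit", "fold_mean"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    rng = np.random.default_rng(seed)
    y_codes = (problem.y == np.unique(problem.y)[1]).astype(int)
    n_min = np.bincount(y_codes).min()
    folds = min(config.cv_folds, n_min)
    if n_min < 2:
        raise ValueError("need at least 2 observations per class")
    acc_actual = np.empty(config.svm_iterations)
    acc_shuffled = np.empty(config.svm_iterations)
    acc_train = np.empty(config.svm_iterations)
    for it in range(config.svm_iterations):
        idx = _balance(y_codes, rng)
        Xb, yb = problem.X[idx], y_codes[idx]
        y_shuf = rng.permutation(yb)
        cv = StratifiedKFold(n_splits=folds, shuffle=True,
                             random_state=int(rng.integers(2 ** 31)))
        a_hits = a_tot = s_hits = 0
        tr_hits = tr_tot = 0
        for train_i, test_i in cv.split(Xb, yb):
            clf = _new_svm().fit(Xb[train_i], yb[train_i])
            pred = clf.predict(Xb[test_i])
            a_hits += int(np.sum(pred == yb[test_i]))
            a_tot += len(test_i)
            tr_pred = clf.predict(Xb[train_i])
            tr_hits += int(np.sum(tr_pred == yb[train_i]))
            tr_tot += len(train_i)
            sclf = _new_svm().fit(Xb[train_i], y_shuf[train_i])
            s_hits += int(np.sum(sclf.predict(Xb[test_i]) == y_shuf[test_i]))
        acc_actual[it] = 100.0 * a_hits / a_tot
        acc_shuffled[it] = 100.0 * s_hits / a_tot
        acc_train[it] = 100.0 * tr_hits / tr_tot
    idx = _balance(y_codes, rng)
    if weight_mode == "refit":
        # one model fit on a balanced draw of all observations
        w = _new_svm().fit(problem.X[idx], y_codes[idx]).coef_.ravel()
    else:
        Xb, yb = problem.X[idx], y_codes[idx]
        cv = StratifiedKFold(n_splits=min(folds, np.bincount(yb).min()),
                             shuffle=True,
                             random_state=int(rng.integers(2 ** 31)))
        ws = [_new_svm().fit(Xb[tr], yb[tr]).coef_.ravel()
              for tr, _ in cv.split(Xb, yb)]
        w = np.mean(ws, axis=0)
    return DecodeResult(
        mean_accuracy_actual=float(acc_actual.mean()),
        mean_accuracy_shuffled=float(acc_shuffled.mean()),
        train_accuracy=float(acc_train.mean()),
        weights=w, normalized_weights=normalize_weights(w),
        n_iterations=config.svm_iterations,
        n_test_splits=config.svm_iterations * folds,
        per_iteration_actual=acc_actual, per_iteration_shuffled=acc_shuffled)


def population_problem(bundle, kind_a: str, kind_b: str, area: str,
                       name: str | None = None) -> DecodeProblem:
    """Two-event decoding problem from a session's population rates.

    Each observation is one event of ``kind_a`` or ``kind_b``; features are
    every ``area`` unit's mean rate over that event's response window.
    """
    from .responses import observation_rates, response_window

    units = bundle.units_in(area)
    if not units:
        raise ValueError(f"no units in area {area!r}")
    rows, labels = [], []
    for kind in (kind_a, kind_b):
        onsets = np.array([e.onset for e in bundle.events_of(kind)], float)
        if onsets.size == 0:
            raise ValueError(f"no events of kind {kind!r}")
        window = response_window(kind, area, bundle.config)
        rates = np.column_stack([
            observation_rates(bundle.spike_train(u.unit_id), onsets, window)
            for u in units])
        rows.append(rates)
        labels.append(np.full(len(onsets), kind))
    return DecodeProblem(np.vstack(rows), np.concatenate(labels),
                         name=name or f"{kind_a}_vs_{kind_b}_{area}")


def normalize_weights(w: np.ndarray) -> np.ndarray:
    """Each weight divided by the Euclidean norm of the population weight vector."""
    w = np.asarray(w, dtype=float)
    norm = np.sqrt(np.sum(w ** 2))
    if norm == 0:
        raise ValueError("all-zero weight vector cannot be normalized")
    return w / norm


@dataclass(frozen=True)
class WeightDistribution:
    variance: float
    kurtosis: float    # raw (non-excess)
    skewness: float    # bias-uncorrected


def weight_distribution_metrics(normalized_weights: np.ndarray
                                ) -> WeightDistribution:
    """Moments of the absolute normalized weights of one session's model."""
    a = np.abs(np.asarray(normalized_weights, dtype=float))
    if a.size < 10:
        raise ValueError("need at least 10 units for distribution metrics")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant weights
        return WeightDistribution(
            variance=float(np.var(a)),
            kurtosis=float(sstats.kurtosis(a, fisher=False, bias=True)),
            skewness=float(sstats.skew(a, bias=True)))


def weight_metric_trends(per_session_weights: list[np.ndarray]
                         ) -> dict[str, TrendResult]:
    """Learning trend of each weight-distribution moment across sessions."""
    rows = [weight_distribution_metrics(w) for w in per_session_weights]
    return {m: learning_trend([getattr(r, m) for r in rows])
            for m in ("variance", "kurtosis", "skewness")}


def conditional_choice_decode(X: np.ndarray, y: np.ndarray,
                              with_cue_mask: np.ndarray, seed: int = 0,
                              config: AnalysisConfig = DEFAULT_CONFIG
                              ) -> dict[str, DecodeResult | None]:
    """Decode choice separately for with-cue and without-cue pushes.

    ``with_cue_mask`` marks pushes preceded by a social-cue fixation within
    1000 ms.  Observation counts are matched across the two conditions by
    subsampling the larger condition before decoding; a condition with
    fewer than two observations per class is skipped (None).
    """
    rng = np.random.default_rng(seed)
    mask = np.asarray(with_cue_mask, dtype=bool)
    out: dict[str, DecodeResult | None] = {}
    n_match = min(mask.sum(), (~mask).sum())
    for name, m in (("with_cue", mask), ("without_cue", ~mask)):
        idx = np.flatnonzero(m)
        if n_match < 4:
            out[name] = None
            continue
        idx = rng.choice(idx, size=n_match, replace=False)
        yc = y[idx]
        if len(np.unique(yc)) < 2 or min(np.bincount(
                (yc == np.unique(yc)[1]).astype(int))) < 2:
            out[name] = None
            continue
        out[name] = decode(DecodeProblem(X[idx], yc, name=name),
                           seed=int(rng.integers(2 ** 31)), config=config)
    return out


def compare_conditions(per_session: list[dict[str, DecodeResult | None]]
                       ) -> dict[str, float]:
    """Paired with-cue vs without-cue comparison across sessions (signed-rank)."""
    with_acc, without_acc = [], []
    for res in per_session:
        a, b = res.get("with_cue"), res.get("without_cue")
        if a is not None and b is not None:
            with_acc.append(a.shuffle_corrected)
            without_acc.append(b.shuffle_corrected)
    if len(with_acc) < 2:
        return {"p": float("nan"), "n_sessions": len(with_acc)}
    return {"p": wilcoxon_signed_rank(with_acc, without_acc),
            "n_sessions": len(with_acc),
            "mean_with_cue": float(np.mean(with_acc)),
            "mean_without_cue": float(np.mean(without_acc))}
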