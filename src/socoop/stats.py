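"""Session-trend statistics shared by all pipeline stages.

Every behavioral and neural metric in the pipeline is tracked across
learning sessions the same way: percent change between the first and last
session, an ordinary least-squares regression of the metric against session
index (two-sided p-value on the slope), and Pearson's correlation
coefficient.  Families of hypothesis tests are corrected with the
Benjamini-Hochberg false-discovery-rate step-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests


def percent_change(x_first: float, x_last: float) -> float:
    """Relative change ``(x_last - x_first) / x_first``.

    Multiply by 100 for a percentage.  Undefined for ``x_first == 0``.
    """
    if x_first == 0:
        raise ValueError("percent_change undefined for x_first == 0")
    return (x_last - x_first) / x_first


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    pearson_r: float
    regression_p: float
    n: int


def learning_trend(values: Sequence[float],
                   sessions: Sequence[float] | None = None) -> TrendResult:
    """OLS fit of a per-session metric against session index.

    Returns the fitted slope, the two-sided p-value for the slope (which,
    with a single predictor, coincides with the test of Pearson's r), and
    Pearson's r itself.  Requires >= 3 sessions; constant input makes r
    undefined and raises.
    """
    y = np.asarray(values, dtype=float)
    x = (np.arange(1, len(y) + 1, dtype=float) if sessions is None
         else np.asarray(sessions, dtype=float))
    if y.size < 3:
        raise ValueError("learning_trend needs at least 3 sessions")
    if y.size != x.size:
        raise ValueError("values and sessions differ in length")
    if np.allclose(y, y[0]):
        raise ValueError("constant values: Pearson r undefined")
    fit = sstats.linregress(x, y)
    return TrendResult(slope=float(fit.slope), intercept=float(fit.intercept),
                       pearson_r=float(fit.rvalue),
                       regression_p=float(fit.pvalue), n=int(y.size))


def fdr_correct(p_values: Sequence[float], alpha: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up decisions at level ``alpha``.

    Returns a boolean rejection mask aligned with the input.  Empty input
    yields an empty mask.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided paired signed-rank p-value; exact method for small n.

    All-zero differences (identical pairing) return p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.all(d == 0):
        return 1.0
    res = sstats.wilcoxon(a, b, zero_method="wilcox", mode="auto",
                          alternative="two-sided")
    return float(res.pvalue)


def rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for unpaired data."""
    res = sstats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue)
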