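"""Chronic-electrode unit stability from waveform-shape PCA.

Each unit contributes a matrix of 100 sampled spike waveforms per session.
All waveforms are projected onto the first seven principal components of a
PCA fit across the supplied sessions, giving each unit a 7-D coefficient
cloud.  The Mahalanobis distance between two clouds,

    MD = sqrt((A_bar - B_bar)^T V^-1 (A_bar - B_bar)),

uses the cloud centroids and the pooled covariance V of the two clouds.
Within-session distances between distinct units, pooled over sessions,
define a null distribution of "different neuron" distances; its 5th
percentile is the stability threshold.  Across-session pairs on the same
electrode below the threshold are linked as the same neuron.  Electrodes
with units in fewer than half the sessions are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

N_PCS = 7


@dataclass(frozen=True)
class WaveformCloud:
    unit_id: str
    session_index: int
    electrode: int
    area: str
    coords: np.ndarray   # n_waveforms x 7 PC coefficients

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass(frozen=True)
class StabilityVerdict:
    electrode: int
    session_a: int
    session_b: int
    unit_a: str
    unit_b: str
    md: float
    threshold: float

    @property
    def stable(self) -> bool:
        return self.md < self.threshold


def waveform_pca(waveforms: dict[tuple[str, int], np.ndarray],
                 meta: dict[str, tuple[int, str]] | None = None,
                 n_components: int = N_PCS) -> list[WaveformCloud]:
    """Project every unit's waveforms into a shared principal-component basis.

    ``waveforms`` maps ``(unit_id, session_index)`` to a (n_samples x
    samples_per_waveform) matrix; all matrices must share the waveform
    length.  ``meta`` optionally maps unit_id to (electrode, area).  PCA is
    fit on all waveforms pooled across the supplied sessions so that
    cross-session distances live in one basis.
    """
    keys = sorted(waveforms)
    mats = [np.asarray(waveforms[k], dtype=float) for k in keys]
    widths = {m.shape[1] for m in mats}
    if len(widths) != 1:
        raise ValueError(f"inconsistent samples per waveform: {sorted(widths)}")
    stacked = np.vstack(mats)
    if min(stacked.shape) < n_components:
        raise ValueError(
            f"waveform matrix rank < {n_components}: shape {stacked.shape}")
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(stacked)
    clouds = []
    row = 0
    for (unit_id, session), m in zip(keys, mats):
        electrode, area = (meta or {}).get(unit_id, (-1, "V4"))
        clouds.append(WaveformCloud(unit_id=unit_id, session_index=session,
                                    electrode=electrode, area=area,
                                    coords=coords[row:row + len(m)]))
        row += len(m)
    return clouds


def mahalanobis_distance(a: np.ndarray, b: np.ndarray,
                         ridge: float = 1e-9,
                         statistic: str = "centroid") -> float:
    """Mahalanobis distance between two coefficient clouds.

    ``centroid`` (default) is the distance between cloud means; V is the
    pooled (sample-size weighted) covariance of the two clouds, and a
    singular V is regularized by adding ``ridge`` times the mean diagonal.
    ``point_mean`` instead averages the per-point distance of each cloud's
    points to the other cloud's centroid (an alternative reading of a
    between-distributions distance).  Both are symmetric in the arguments.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("clouds must share the PC basis dimension")
    if statistic not in ("centroid", "point_mean"):
        raise ValueError(f"unknown statistic {statistic!r}")
    d = a.mean(axis=0) - b.mean(axis=0)
    na, nb = len(a), len(b)
    cov_a = np.cov(a, rowvar=False) if na > 1 else np.zeros((a.shape[1],) * 2)
    cov_b = np.cov(b, rowvar=False) if nb > 1 else np.zeros((b.shape[1],) * 2)
    wa = max(na - 1, 0)
    wb = max(nb - 1, 0)
    v = (wa * np.atleast_2d(cov_a) + wb * np.atleast_2d(cov_b)) / max(wa + wb, 1)
    try:
        vinv = np.linalg.inv(v)
    except np.linalg.LinAlgError:
        scale = max(np.trace(v) / v.shape[0], 1.0)
        warnings.warn("singular pooled covariance; applying ridge")
        vinv = np.linalg.inv(v + ridge * scale * np.eye(v.shape[0]))
    if statistic == "point_mean":
        ca, cb = a.mean(axis=0), b.mean(axis=0)
        da = a - cb
        db = b - ca
        dist_a = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", da, vinv, da), 0))
        dist_b = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", db, vinv, db), 0))
        return float(0.5 * (dist_a.mean() + dist_b.mean()))
    return float(np.sqrt(max(d @ vinv @ d, 0.0)))


def within_session_distances(clouds: list[WaveformCloud]) -> np.ndarray:
    """Distances between all distinct-unit pairs within each session, pooled."""
    out = []
    sessions = sorted({c.session_index for c in clouds})
    for s in sessions:
        cs = [c for c in clouds if c.session_index == s]
        for i in range(len(cs)):
            for j in range(i + 1, len(cs)):
                out.append(mahalanobis_distance(cs[i].coords, cs[j].coords))
    return np.asarray(out)


def stability_threshold(distances: np.ndarray, percentile: float = 5.0) -> float:
    """5th percentile (linear interpolation) of the distinct-neuron distances."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no within-session distances supplied")
    if d.size < 20:
        warnings.warn("fewer than 20 pairwise distances; percentile unstable")
    return float(np.percentile(d, percentile, method="linear"))


@dataclass
class StabilityReport:
    verdicts: list[StabilityVerdict]
    threshold: float
    n_stable: dict[str, int]          # per area
    n_total: dict[str, int]
    excluded_electrodes: list[int]

    def stable_fraction(self, area: str) -> float:
        tot = self.n_total.get(area, 0)
        return self.n_stable.get(area, 0) / tot if tot else float("nan")


def stable_fraction_percent(n_stable: int, n_total: int) -> float:
    """Stable-unit percentage from raw counts (100 * n_stable / n_total)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_stable / n_total


def classify_channel_stability(clouds: list[WaveformCloud],
                               threshold: float | None = None,
                               min_session_fraction: float = 0.5
                               ) -> StabilityReport:
    """Link same-electrode units across consecutive sessions via the MD threshold.

    A unit in session s is "stable" if a unit on the same electrode in the
    next session it appears in lies below the threshold (no transitive
    linking across gaps of more than one session).  The stable fraction per
    area counts stably linked unit-sessions over unit-sessions that have an
    eligible next-session comparison on included electrodes.  Electrodes
    recorded in fewer than ``min_session_fraction`` of sessions are excluded
    from the denominator.
    """
    if threshold is None:
        threshold = stability_threshold(within_session_distances(clouds))
    sessions = sorted({c.session_index for c in clouds})
    n_sessions = len(sessions)
    by_elec: dict[int, list[WaveformCloud]] = {}
    for c in clouds:
        by_elec.setdefault(c.electrode, []).append(c)

    verdicts: list[StabilityVerdict] = []
    n_stable: dict[str, int] = {}
    n_total: dict[str, int] = {}
    excluded = []
    for elec, cs in sorted(by_elec.items()):
        present = sorted({c.session_index for c in cs})
        if len(present) < min_session_fraction * n_sessions:
            excluded.append(elec)
            continue
        for sa, sb in zip(present, present[1:]):
            if sb - sa > 1:   # chain broken across a gap
                continue
            for ca in (c for c in cs if c.session_index == sa):
                n_total[ca.area] = n_total.get(ca.area, 0) + 1
                best = None
                for cb in (c for c in cs if c.session_index == sb):
                    md = mahalanobis_distance(ca.coords, cb.coords)
                    v = StabilityVerdict(elec, sa, sb, ca.unit_id, cb.unit_id,
                                         md, threshold)
                    verdicts.append(v)
                    if best is None or md < best.md:
                        best = v
                if best is not None and best.stable:
                    n_stable[ca.area] = n_stable.get(ca.area, 0) + 1
    return StabilityReport(verdicts=verdicts, threshold=threshold,
                           n_stable=n_stable, n_total=n_total,
                           excluded_electrodes=excluded)
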