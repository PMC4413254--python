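"""Field-of-view statistics.

Ensonified cone-base areas and measured/predicted area ratios, active-
sonar detection range, the beamwidth-vs-range regression, and the
cluster + ANOVA comparison of beamwidth groups against distance to
target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import f_oneway

__all__ = [
    "ensonified_area",
    "area_ratio_series",
    "long_range_reference_beamwidth",
    "detection_range",
    "beamwidth_range_regression",
    "cluster_anova",
    "RegressionResult",
    "ClusterAnovaResult",
]

LONG_RANGE_THRESHOLD_M = 2.0
DETECTION_THRESHOLD_DB = 27.0
TARGET_STRENGTH_DB = -36.0


def ensonified_area(beamwidth_deg, range_m):
    """Base area (m^2) of the cone with height ``range_m`` and opening
    angle ``beamwidth_deg``: pi * (r * tan(bw/2))^2."""
    bw = np.asarray(beamwidth_deg, dtype=float)
    r = np.asarray(range_m, dtype=float)
    if np.any(bw <= 0) or np.any(bw >= 180) or np.any(r <= 0):
        raise ValueError("need 0 < beamwidth < 180 deg and range > 0")
    out = np.pi * (r * np.tan(np.radians(bw / 2.0))) ** 2
    return float(out) if out.ndim == 0 else out


def long_range_reference_beamwidth(
    beamwidth_deg: np.ndarray,
    range_m: np.ndarray,
    threshold_m: float = LONG_RANGE_THRESHOLD_M,
) -> float:
    """Median beamwidth of clicks emitted beyond the long-range threshold
    (> 2 m)."""
    bw = np.asarray(beamwidth_deg, dtype=float)
    r = np.asarray(range_m, dtype=float)
    m = r > threshold_m
    if not m.any():
        raise ValueError("no long-range clicks to form the reference")
    return float(np.median(bw[m]))


def area_ratio_series(
    beamwidth_deg: np.ndarray, reference_beamwidth_deg: float
) -> np.ndarray:
    """Measured/predicted area ratio per click; the cone height cancels:
    (tan(bw/2) / tan(bw_ref/2))^2."""
    bw = np.asarray(beamwidth_deg, dtype=float)
    t_ref = math.tan(math.radians(reference_beamwidth_deg / 2.0))
    return (np.tan(np.radians(bw / 2.0)) / t_ref) ** 2


def detection_range(
    source_level_db: float,
    detection_threshold_db: float = DETECTION_THRESHOLD_DB,
    target_strength_db: float = TARGET_STRENGTH_DB,
) -> float:
    """Largest r with SL - 40*log10(r) + TS >= DT:
    r = 10^((SL + TS - DT) / 40) (two-way spherical spreading)."""
    return 10.0 ** ((source_level_db + target_strength_db - detection_threshold_db) / 40.0)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    f_statistic: float
    r_squared: float
    p_value: float
    n: int


def beamwidth_range_regression(
    beamwidth_deg: np.ndarray, range_m: np.ndarray
) -> RegressionResult:
    """OLS of beamwidth on target range (pooled over trials)."""
    import statsmodels.api as sm

    bw = np.asarray(beamwidth_deg, dtype=float)
    r = np.asarray(range_m, dtype=float)
    if bw.size < 3:
        raise ValueError("need at least three records")
    if np.ptp(r) == 0:
        raise ValueError("zero variance in range")
    model = sm.OLS(bw, sm.add_constant(r)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        f_statistic=float(model.fvalue),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(bw.size),
    )


@dataclass
class ClusterAnovaResult:
    labels: np.ndarray  # 1..k, ordered by ascending mean beamwidth
    cluster_mean_beamwidth: np.ndarray
    cluster_mean_distance: np.ndarray
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # pairwise comparisons on distance


def cluster_anova(
    beamwidth_deg: np.ndarray,
    distance_m: np.ndarray,
    n_clusters: int = 3,
) -> ClusterAnovaResult:
    """Centroid-linkage hierarchical clustering of raw (non-standardized)
    beamwidths cut at ``n_clusters``, one-way ANOVA of distance to target
    across clusters, and Tukey-Kramer pairwise comparisons.

    Cluster labels are renumbered by ascending mean beamwidth, making them
    invariant to input order.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    bw = np.asarray(beamwidth_deg, dtype=float)
    dist = np.asarray(distance_m, dtype=float)
    if np.unique(bw).size < n_clusters:
        raise ValueError("fewer distinct beamwidths than clusters; degenerate")
    z = linkage(bw[:, None], method="centroid")
    raw = fcluster(z, t=n_clusters, criterion="maxclust")
    order = np.argsort([bw[raw == c].mean() for c in np.unique(raw)])
    remap = {c: i + 1 for i, c in enumerate(np.unique(raw)[order])}
    labels = np.array([remap[c] for c in raw])
    groups = [dist[labels == c] for c in range(1, n_clusters + 1)]
    f_stat, p = f_oneway(*groups)
    tk = pairwise_tukeyhsd(dist, labels)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return ClusterAnovaResult(
        labels=labels,
        cluster_mean_beamwidth=np.array([bw[labels == c].mean() for c in range(1, n_clusters + 1)]),
        cluster_mean_distance=np.array([g.mean() for g in groups]),
        anova_f=float(f_stat),
        anova_p=float(p),
        tukey=tukey,
    )
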