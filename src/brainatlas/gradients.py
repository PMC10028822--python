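"""Cluster discreteness and spatial expression gradients.

Some subclasses split into well-separated clusters; others vary
continuously, with cluster boundaries that are arbitrary cuts through a
gradient.  Neighbourhood purity quantifies this: the fraction of a
cell's 50 nearest expression-space neighbors sharing its cluster label.
Mean purity per cluster is the cluster's discreteness, and the median
over a subclass's clusters summarizes the subclass.  Spatial gradients
are scored by a per-cell axis (PC1 of the standardized expression, or a
principal-curve pseudotime variant) correlated against a spatial
coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .integration import standardize

__all__ = [
    "DiscretenessReport",
    "GradientAxis",
    "neighbourhood_purity",
    "discreteness",
    "gradient_axis",
    "spatial_correlation",
]


@dataclass
class DiscretenessReport:
    purity: np.ndarray  # per cell, [0, 1]
    cluster_discreteness: pd.Series  # per cluster mean purity
    subclass_discreteness: pd.Series  # per subclass median of cluster values

    def __post_init__(self) -> None:
        if np.any((self.purity < 0) | (self.purity > 1)):
            raise ValueError("purity must lie in [0, 1]")


@dataclass
class GradientAxis:
    scores: np.ndarray  # per-cell axis position
    method: str  # "pc1" | "pseudotime"
    orientation_sign: int
    r: float  # Pearson r against the orienting coordinate

    def __post_init__(self) -> None:
        if not -1 <= self.r <= 1:
            raise ValueError("r must lie in [-1, 1]")


def neighbourhood_purity(
    expr: np.ndarray,
    cluster_labels: np.ndarray,
    k: int = 50,
    n_pcs: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Fraction of same-cluster cells among k nearest expression neighbors.

    Neighbors are found in the top-``n_pcs`` PCA space of the
    standardized expression matrix; purity is invariant to global
    rescaling of the input.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(cluster_labels, dtype=object)
    n = len(expr)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} cells")
    z = standardize(expr)
    d = min(n_pcs, z.shape[1], n - 1)
    pcs = PCA(n_components=d, random_state=seed).fit_transform(z)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, nbrs = nn.kneighbors(pcs)
    return (labels[nbrs[:, 1:]] == labels[:, None]).mean(axis=1)


def discreteness(
    purity: np.ndarray,
    cluster_labels: np.ndarray,
    subclass_of_cluster: dict,
) -> DiscretenessReport:
    """Per-cluster mean purity and per-subclass median cluster discreteness."""
    s = pd.Series(np.asarray(purity, dtype=float))
    cl = pd.Series(np.asarray(cluster_labels, dtype=object))
    cluster_disc = s.groupby(cl).mean()
    sub = cluster_disc.groupby(
        cluster_disc.index.map(subclass_of_cluster)
    ).median()
    sub = sub[sub.index.notna()]
    return DiscretenessReport(
        purity=np.asarray(purity, dtype=float),
        cluster_discreteness=cluster_disc,
        subclass_discreteness=sub,
    )


def _principal_curve_order(pcs: np.ndarray, n_segments: int = 20) -> np.ndarray:
    """PC1-seeded pseudotime: project onto a polyline through the running
    means of PC coordinates along PC1 bins.  A light-weight principal-
    curve stand-in adequate for monotone gradients."""
    order = np.argsort(pcs[:, 0], kind="stable")
    bins = np.array_split(order, n_segments)
    knots = np.array([pcs[b].mean(axis=0) for b in bins if len(b)])
    # arclength position of each cell's nearest segment projection
    seg = np.diff(knots, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    t = np.empty(len(pcs))
    for i, p in enumerate(pcs):
        best, best_d = 0.0, np.inf
        for s in range(len(seg)):
            v = seg[s]
            L2 = v @ v
            u = 0.0 if L2 == 0 else np.clip((p - knots[s]) @ v / L2, 0, 1)
            proj = knots[s] + u * v
            d = np.sum((p - proj) ** 2)
            if d < best_d:
                best_d, best = d, cum[s] + u * seg_len[s]
        t[i] = best
    return t


def gradient_axis(
    expr_subset: np.ndarray,
    orient_against: np.ndarray,
    method: str = "pc1",
    n_pcs: int = 10,
    log_normalize: bool = True,
    seed: int = 0,
) -> GradientAxis:
    """Per-cell gradient score from expression.

    ``pc1`` scores cells by the first principal component of the
    standardized expression; ``pseudotime`` orders them along a
    PC1-seeded principal curve.  The sign is flipped so the Pearson
    correlation with ``orient_against`` is non-negative.

    With ``log_normalize`` (the default for raw counts) cells are
    total-normalized and log1p-transformed before z-scoring; pass False
    when the input is already on a normalized scale.
    """
    expr_subset = np.asarray(expr_subset, dtype=float)
    if len(expr_subset) < 3:
        raise ValueError("need at least 3 cells")
    if log_normalize:
        z = standardize(expr_subset)
    else:
        mu = expr_subset.mean(axis=0)
        sd = expr_subset.std(axis=0)
        constant = sd <= 1e-10 * (np.abs(mu) + 1.0)
        sd[constant] = 1.0
        z = (expr_subset - mu) / sd
        z[:, constant] = 0.0
    if np.allclose(z, 0):
        raise ValueError("zero-variance expression")
    if method == "pc1":
        scores = PCA(n_components=1, random_state=seed).fit_transform(z)[:, 0]
    elif method == "pseudotime":
        d = min(n_pcs, z.shape[1], len(z) - 1)
        pcs = PCA(n_components=d, random_state=seed).fit_transform(z)
        scores = _principal_curve_order(pcs)
    else:
        raise ValueError("method must be 'pc1' or 'pseudotime'")
    r = float(pearsonr(scores, np.asarray(orient_against, dtype=float)).statistic)
    sign = -1 if r < 0 else 1
    return GradientAxis(
        scores=sign * scores, method=method, orientation_sign=sign, r=abs(r)
    )


def spatial_correlation(
    values: np.ndarray, coordinate: np.ndarray, conf: float = 0.95
) -> dict:
    """Pearson r between a per-cell scalar and a spatial coordinate, with
    a Fisher-z confidence interval.  Zero variance flags the result as
    undefined instead of raising."""
    values = np.asarray(values, dtype=float)
    coordinate = np.asarray(coordinate, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 cells")
    if np.std(values) == 0 or np.std(coordinate) == 0:
        return {"r": np.nan, "ci": (np.nan, np.nan), "n": len(values), "defined": False}
    res = pearsonr(values, coordinate)
    ci = res.confidence_interval(confidence_level=conf)
    return {
        "r": float(res.statistic),
        "ci": (float(ci.low), float(ci.high)),
        "n": len(values),
        "defined": True,
    }
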