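"""Spatial-module delineation from local cell-type composition.

Each cell is described by a distance-weighted census of the cell types
among its 50 spatially nearest neighbors: neighbor j of cell i gets
weight exp(-(D_ij / D0_i)^2), where the scaling distance D0_i adapts to
local density (level 1: twice the distance to the 5th nearest neighbor;
level 2: that distance itself, for finer structure).  The per-type
weight sums are L2-normalized into a composition vector, and Leiden
community detection on the kNN graph of those vectors yields spatial
modules — molecularly defined regions.  Level-2 modules are computed
within each level-1 module separately, on neurons only, with the
subclass-based vector concatenated to the cluster-based vector.
"""

from __future__ import annotations

import logging

import igraph
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .core_io import CellTable
from .region_stats import EnrichmentMatrix, enrichment_scores

logger = logging.getLogger("brainatlas")

__all__ = [
    "composition_weights",
    "composition_vectors",
    "cluster_spatial_modules",
    "merge_similar_modules",
    "delineate_modules",
    "level2_modules",
    "module_enrichment",
]


def composition_weights(distances: np.ndarray, d0: float) -> np.ndarray:
    """Neighbor weight exp(-(D/D0)^2): 1 at distance 0, 1/e at D0."""
    return np.exp(-((np.asarray(distances, dtype=float) / d0) ** 2))


def _vectors_for_section(
    pts: np.ndarray, type_codes: np.ndarray, n_types: int, level: int, k: int
) -> np.ndarray:
    n = len(pts)
    if n < 6:
        raise ValueError("fewer than 6 eligible cells: scaling distance undefined")
    kk = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=kk + 1).fit(pts)
    dist, nbrs = nn.kneighbors(pts)
    d5 = dist[:, 5]  # distance to 5th nearest neighbor
    d0 = 2 * d5 if level == 1 else d5
    d0 = np.where(d0 == 0, np.finfo(float).tiny, d0)
    w = np.exp(-((dist[:, 1:] / d0[:, None]) ** 2))
    vec = np.zeros((n, n_types))
    rows = np.repeat(np.arange(n), kk)
    np.add.at(vec, (rows, type_codes[nbrs[:, 1:]].ravel()), w.ravel())
    return vec


def composition_vectors(
    cells: CellTable,
    level: int = 1,
    k: int = 50,
    eligible: np.ndarray | None = None,
) -> tuple[np.ndarray, list]:
    """Distance-weighted local cell-type composition vectors, L2-normalized.

    Level 1 builds a vector over subclasses; level 2 concatenates the
    subclass vector with the cluster vector.  Neighborhoods never cross
    sections.  ``eligible`` restricts which cells participate (callers
    exclude vascular/immune cells at level 1, keep only neurons at level
    2); vectors are returned for eligible cells in table order, along
    with the feature (type) names.
    """
    if level not in (1, 2):
        raise ValueError("level must be 1 or 2")
    mask = np.ones(cells.n_cells, bool) if eligible is None else np.asarray(eligible, bool)
    sub = cells.meta["subclass_label"].to_numpy(dtype=object)[mask]
    features = sorted(set(sub))
    blocks = [(sub, features)]
    if level == 2:
        clu = cells.meta["cluster_label"].to_numpy(dtype=object)[mask]
        blocks.append((clu, sorted(set(clu))))
    xy = cells.meta[["x", "y"]].to_numpy()[mask]
    section = cells.meta["section_id"].to_numpy()[mask]
    n = mask.sum()
    parts = []
    names: list = []
    for labels, feats in blocks:
        code_of = {t: i for i, t in enumerate(feats)}
        codes = np.array([code_of[t] for t in labels])
        block = np.zeros((n, len(feats)))
        for sec in np.unique(section):
            idx = np.flatnonzero(section == sec)
            block[idx] = _vectors_for_section(
                xy[idx], codes[idx], len(feats), level, k
            )
        parts.append(block)
        names += list(feats)
    vec = np.hstack(parts)
    nrm = np.linalg.norm(vec, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return vec / nrm, names


def cluster_spatial_modules(
    vectors: np.ndarray, knn: int = 15, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Leiden community detection on the kNN graph of composition vectors.

    Exactly duplicated vectors are collapsed to one graph node first (ties
    among identical points would otherwise split arbitrarily), then the
    community label is broadcast back.
    """
    vectors = np.asarray(vectors)
    n = len(vectors)
    if n == 0:
        return np.empty(0, dtype=int)
    uniq, inverse = np.unique(vectors, axis=0, return_inverse=True)
    m = len(uniq)
    if m == 1:
        return np.zeros(n, dtype=int)
    kk = min(knn, m - 1)
    nn = NearestNeighbors(n_neighbors=kk + 1).fit(uniq)
    _, nbrs = nn.kneighbors(uniq)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(nbrs) for j in row[1:]}
    g = igraph.Graph(n=m, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)[inverse]


def merge_similar_modules(
    vectors: np.ndarray, labels: np.ndarray, threshold: float = 0.9
) -> np.ndarray:
    """Iteratively merge the module pair with the highest centroid cosine
    similarity above ``threshold``.

    Leiden at its default resolution over-fragments region-scale
    structure; merging compositionally indistinguishable modules is the
    programmatic counterpart of the manual curation step that merges
    clusters lacking clear spatial boundaries.
    """
    labels = np.asarray(labels).copy()
    while True:
        uniq = sorted(set(labels))
        if len(uniq) < 2:
            return labels
        cents = np.vstack([vectors[labels == u].mean(axis=0) for u in uniq])
        nrm = np.linalg.norm(cents, axis=1, keepdims=True)
        sim = (cents / nrm) @ (cents / nrm).T
        np.fill_diagonal(sim, -1.0)
        i, j = np.unravel_index(np.argmax(sim), sim.shape)
        if sim[i, j] <= threshold:
            return labels
        keep, drop = sorted((uniq[i], uniq[j]))
        labels[labels == drop] = keep


def delineate_modules(
    cells: CellTable,
    level: int = 1,
    k: int = 50,
    knn: int = 15,
    resolution: float = 1.0,
    merge_threshold: float | None = 0.9,
    seed: int = 0,
    eligible: np.ndarray | None = None,
) -> np.ndarray:
    """Full module-delineation procedure: composition vectors, Leiden
    clustering, and centroid-cosine merging of indistinct modules."""
    vec, _ = composition_vectors(cells, level=level, k=k, eligible=eligible)
    labels = cluster_spatial_modules(vec, knn=knn, resolution=resolution, seed=seed)
    if merge_threshold is not None:
        labels = merge_similar_modules(vec, labels, merge_threshold)
    return labels


def level2_modules(
    cells: CellTable,
    level1_labels: np.ndarray,
    is_neuron: np.ndarray,
    k: int = 50,
    knn: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Nested level-2 modules, computed per level-1 module on neurons only.

    Returns per-cell labels '<level1>.<local>'; non-neurons and modules
    with fewer than 6 neurons get no finer split (single local module).
    """
    level1_labels = np.asarray(level1_labels, dtype=object)
    is_neuron = np.asarray(is_neuron, bool)
    out = pd.Series([None] * cells.n_cells, index=cells.cell_ids, dtype=object)
    for mod in sorted(set(level1_labels[is_neuron])):
        sel = (level1_labels == mod) & is_neuron
        idx = np.flatnonzero(sel)
        if len(idx) < 6:
            out.iloc[idx] = f"{mod}.0"
            continue
        sub = cells.subset(sel)
        vec, _ = composition_vectors(sub, level=2, k=k)
        local = cluster_spatial_modules(vec, knn=knn, resolution=resolution, seed=seed)
        out.iloc[idx] = [f"{mod}.{m}" for m in local]
    return out


def module_enrichment(
    types: np.ndarray, module_labels: np.ndarray
) -> EnrichmentMatrix:
    """Fraction-mode enrichment of cell types across spatial modules."""
    return enrichment_scores(types, module_labels, mode="fraction")
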