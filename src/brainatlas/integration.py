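"""Reference/measured co-embedding, anchor finding, two-round label
transfer with confidence scores, and transcriptome-wide imputation.

The measured (panel-restricted, spatially resolved) dataset is integrated
with a reference single-cell dataset by canonical correlation analysis on
the shared genes.  Mutual nearest neighbors across the two datasets in
CCA space are "anchors".  A measured cell's label is the most frequent
label among its 100 nearest anchor reference-cells in a joint PCA space,
and the confidence score is that label's frequency.

Because one pass cannot resolve thousands of clusters, the transfer runs
in two rounds: round 1 transfers coarse integration-partition labels
(groups of subclasses transcriptionally close to each other), round 2
runs independently within each partition on that partition's highly
variable genes and transfers subclass and cluster labels.  A label is
only right if both rounds were right, so final confidences are the
product of the round-2 confidence and the partition confidence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core_io import CellTable, ReferenceDataset

logger = logging.getLogger("brainatlas")

__all__ = [
    "Embedding",
    "AnchorSet",
    "TransferResult",
    "standardize",
    "positive_dispersion_genes",
    "build_partitions",
    "cca_coembed",
    "find_anchors",
    "transfer_labels",
    "two_round_transfer",
    "impute",
    "cosine_assign",
]


@dataclass
class Embedding:
    coords: np.ndarray  # (n_cells, dims)
    dataset: str  # "reference" | "measured"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding must be finite")

    @property
    def dims(self) -> int:
        return self.coords.shape[1]


@dataclass
class AnchorSet:
    """Mutual-nearest-neighbor (reference cell, measured cell) pairs."""

    ref_idx: np.ndarray
    meas_idx: np.ndarray

    def __len__(self) -> int:
        return len(self.ref_idx)


def standardize(counts: np.ndarray, target_total: float = 1000.0) -> np.ndarray:
    """Total-normalize each cell to ``target_total``, log1p, z-score genes.

    Constant genes z-score to an all-zero column.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("all-zero cell cannot be standardized")
    x = np.log1p(counts / totals * target_total)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    constant = sd <= 1e-10 * (np.abs(mu) + 1.0)
    sd[constant] = 1.0
    z = (x - mu) / sd
    z[:, constant] = 0.0
    return z


def lognormalize(counts: np.ndarray, target_total: float = 1000.0) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(counts / totals * target_total)


def positive_dispersion_genes(counts: np.ndarray, genes: list[str]) -> list[str]:
    """Genes with positive log dispersion (variance/mean above 1).

    Totals are normalized to the median per-cell total, not an arbitrary
    target, so the Poisson baseline (dispersion 1) is preserved and the
    threshold is scale-free.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    norm = counts / totals * np.median(totals)
    mean = norm.mean(axis=0)
    var = norm.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    return [g for g, d in zip(genes, disp) if d > 1.0]


# ---------------------------------------------------------------------------
# integration partitions


def _balanced_kway_cut(
    weights: np.ndarray, sizes: np.ndarray, k: int, seed: int,
    n_restarts: int = 8, balance_tol: float = 0.34,
) -> np.ndarray:
    """Balanced k-way partition of a weighted graph minimizing cut weight.

    Greedy seeded initialization followed by single-node move refinement,
    best of several restarts.  Balance constraint: each part's total node
    size stays below (1 + tol) * total/k.
    """
    n = len(sizes)
    cap = (1 + balance_tol) * sizes.sum() / k
    rng = np.random.default_rng(seed)
    best_labels, best_cut = None, math.inf

    def cut_of(labels):
        mask = labels[:, None] != labels[None, :]
        return weights[mask].sum() / 2

    for _ in range(n_restarts):
        order = np.argsort(-sizes + rng.uniform(0, 1e-9, n))
        order = rng.permutation(n) if rng.uniform() < 0.5 else order
        labels = -np.ones(n, dtype=int)
        load = np.zeros(k)
        for node in order:
            gains = np.array(
                [
                    weights[node, labels == p].sum() if np.any(labels == p) else 0.0
                    for p in range(k)
                ]
            )
            feasible = load + sizes[node] <= cap
            if not feasible.any():
                feasible = load == load.min()
            cand = np.flatnonzero(feasible)
            p = cand[np.lexsort((load[cand], -gains[cand]))][0]
            labels[node] = p
            load[p] += sizes[node]
        improved = True
        while improved:
            improved = False
            for node in range(n):
                cur = labels[node]
                attach = np.array(
                    [weights[node, labels == p].sum() for p in range(k)]
                )
                attach[cur] = weights[node, (labels == cur) & (np.arange(n) != node)].sum()
                for p in np.argsort(-attach):
                    if p == cur:
                        break
                    if load[p] + sizes[node] <= cap and attach[p] > attach[cur]:
                        load[cur] -= sizes[node]
                        load[p] += sizes[node]
                        labels[node] = p
                        improved = True
                        break
        c = cut_of(labels)
        if c < best_cut:
            best_cut, best_labels = c, labels.copy()
    return best_labels


def build_partitions(
    ref: ReferenceDataset,
    n_parts: int | None = None,
    pca_dims: int = 100,
    knn: int = 15,
    seed: int = 0,
) -> dict:
    """Group subclasses into integration partitions.

    A subclass connectivity graph is built from the cell-level kNN graph
    in PCA space of the standardized counts: the weight of a subclass
    edge is the number of kNN edges connecting cells of the two
    subclasses.  Subclasses are then split into ``n_parts`` balanced
    parts (by cell count) minimizing the cut weight.  The default part
    count scales as ceil(#subclasses / 6.4), minimum 1.

    Returns subclass -> partition index, and stores per-cell partition
    labels on ``ref.partition_labels``.
    """
    subclasses = sorted(set(ref.subclass_labels))
    if n_parts is None:
        n_parts = max(1, math.ceil(len(subclasses) / 6.4))
    if n_parts > len(subclasses):
        raise ValueError("n_parts exceeds the number of subclasses")
    z = standardize(ref.counts)
    dims = min(pca_dims, z.shape[0] - 1, z.shape[1])
    pcs = PCA(n_components=dims, random_state=seed).fit_transform(z)
    nn = NearestNeighbors(n_neighbors=min(knn + 1, len(pcs))).fit(pcs)
    _, nbrs = nn.kneighbors(pcs)
    sc_index = {s: i for i, s in enumerate(subclasses)}
    cell_sc = np.array([sc_index[s] for s in ref.subclass_labels])
    n_sc = len(subclasses)
    weights = np.zeros((n_sc, n_sc))
    for i, row in enumerate(nbrs):
        a = cell_sc[i]
        for j in row[1:]:
            b = cell_sc[j]
            weights[a, b] += 1
            weights[b, a] += 1
    np.fill_diagonal(weights, 0)
    sizes = np.bincount(cell_sc, minlength=n_sc).astype(float)
    if n_parts == 1:
        labels = np.zeros(n_sc, dtype=int)
    else:
        labels = _balanced_kway_cut(weights, sizes, n_parts, seed)
    mapping = {s: int(labels[sc_index[s]]) for s in subclasses}
    ref.partition_labels = np.array(
        [mapping[s] for s in ref.subclass_labels], dtype=int
    )
    logger.info("build_partitions: %d subclasses -> %d parts", n_sc, n_parts)
    return mapping


# ---------------------------------------------------------------------------
# CCA co-embedding and anchors


def cca_coembed(
    ref_z: np.ndarray,
    meas_z: np.ndarray,
    dims: int = 100,
    downsample: int = 100_000,
    seed: int = 0,
) -> tuple[Embedding, Embedding]:
    """Co-embed two standardized datasets by diagonal CCA.

    With unpaired cells the shared axis is genes: the canonical vectors
    are the singular vectors of the cell-by-cell cross-product X Y^T of
    the (downsampled) standardized datasets, computed economically
    through QR factorizations.  The gene-space linear maps recovered
    from the singular vectors project the full datasets, and each cell's
    embedding vector is L2-normalized.
    """
    ref_z = np.asarray(ref_z, dtype=float)
    meas_z = np.asarray(meas_z, dtype=float)
    if ref_z.shape[1] != meas_z.shape[1]:
        raise ValueError("gene columns must be aligned")
    max_dims = min(ref_z.shape[1], ref_z.shape[0], meas_z.shape[0])
    if dims > max_dims:
        raise ValueError(f"dims {dims} exceeds min(genes, cells) = {max_dims}")
    rng = np.random.default_rng(seed)

    def _down(x):
        if x.shape[0] <= downsample:
            return x
        return x[rng.choice(x.shape[0], downsample, replace=False)]

    xd, yd = _down(ref_z), _down(meas_z)
    qx, rx = np.linalg.qr(xd)
    qy, ry = np.linalg.qr(yd)
    u_s, s, vt_s = np.linalg.svd(rx @ ry.T)
    u_s, v_s, s = u_s[:, :dims], vt_s[:dims].T, s[:dims]
    s_inv = 1.0 / np.where(s > 1e-12, s, 1.0)
    # gene-space canonical maps: project any cell profile into CCA space
    w_ref = yd.T @ (qy @ v_s) * s_inv
    w_meas = xd.T @ (qx @ u_s) * s_inv

    def _norm(e):
        nrm = np.linalg.norm(e, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        return e / nrm

    return (
        Embedding(_norm(ref_z @ w_ref), "reference"),
        Embedding(_norm(meas_z @ w_meas), "measured"),
    )


def find_anchors(emb_ref: Embedding, emb_meas: Embedding, k: int = 5) -> AnchorSet:
    """All cross-dataset mutual k-nearest-neighbor pairs."""
    if emb_ref.dims != emb_meas.dims:
        raise ValueError("embeddings must share dimensionality")
    if len(emb_ref.coords) == 0 or len(emb_meas.coords) == 0:
        raise ValueError("empty embedding")
    k_r = min(k, len(emb_ref.coords))
    k_m = min(k, len(emb_meas.coords))
    nn_ref = NearestNeighbors(n_neighbors=k_r).fit(emb_ref.coords)
    nn_meas = NearestNeighbors(n_neighbors=k_m).fit(emb_meas.coords)
    _, meas_to_ref = nn_ref.kneighbors(emb_meas.coords)  # per meas: k ref
    _, ref_to_meas = nn_meas.kneighbors(emb_ref.coords)  # per ref: k meas
    fwd = {(r, m) for m, row in enumerate(meas_to_ref) for r in row}
    pairs = sorted(
        (r, m)
        for r, row in enumerate(ref_to_meas)
        for m in row
        if (r, m) in fwd
    )
    return AnchorSet(
        ref_idx=np.array([p[0] for p in pairs], dtype=int),
        meas_idx=np.array([p[1] for p in pairs], dtype=int),
    )


def transfer_labels(
    anchor_coords: np.ndarray,
    anchor_labels: np.ndarray,
    meas_coords: np.ndarray,
    k_anchor: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Vote labels from the nearest anchors in a joint space.

    For each measured cell, its ``k_anchor`` nearest anchor reference-
    cells vote; the assigned label is the most frequent one (ties broken
    lexicographically) and the confidence is that label's fraction.
    """
    if len(anchor_coords) == 0:
        raise ValueError("no anchors")
    anchor_labels = np.asarray(anchor_labels, dtype=object)
    k = min(k_anchor, len(anchor_coords))
    nn = NearestNeighbors(n_neighbors=k).fit(anchor_coords)
    _, nbrs = nn.kneighbors(meas_coords)
    labels = np.empty(len(meas_coords), dtype=object)
    confs = np.empty(len(meas_coords))
    for i, row in enumerate(nbrs):
        votes = pd.Series(anchor_labels[row]).value_counts()
        top = votes.max()
        labels[i] = sorted(votes.index[votes == top])[0]
        confs[i] = top / k
    return labels, confs


@dataclass
class TransferResult:
    """Per-measured-cell labels and confidences from two-round transfer.

    Subclass/cluster confidences are already adjusted (multiplied by the
    partition confidence); pass flags apply the 0.8 / 0.5 gates.
    """

    table: pd.DataFrame  # indexed by measured cell_id

    def __post_init__(self) -> None:
        for col in ("subclass_confidence", "cluster_confidence", "partition_confidence"):
            v = self.table[col].to_numpy(dtype=float)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{col} outside [0, 1]")


def _joint_pca(
    ref_z: np.ndarray, meas_z: np.ndarray, dims: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    combined = np.vstack([ref_z, meas_z])
    d = min(dims, combined.shape[0] - 1, combined.shape[1])
    pcs = PCA(n_components=d, random_state=seed).fit_transform(combined)
    return pcs[: len(ref_z)], pcs[len(ref_z) :]


def _one_round(
    ref_counts: np.ndarray,
    meas_counts: np.ndarray,
    ref_labels_by_kind: dict,
    cca_dims: int,
    pca_dims: int,
    anchor_k: int,
    transfer_k: int,
    downsample: int,
    seed: int,
) -> tuple[dict, AnchorSet, np.ndarray, np.ndarray]:
    """Standardize, co-embed, anchor, and vote each label kind.

    Returns ({kind: (labels, confidences)}, anchors, ref joint-PCA
    coords, measured joint-PCA coords).
    """
    ref_z = standardize(ref_counts)
    meas_z = standardize(meas_counts)
    dims = min(cca_dims, ref_z.shape[1], ref_z.shape[0], meas_z.shape[0])
    emb_ref, emb_meas = cca_coembed(ref_z, meas_z, dims, downsample, seed)
    anchors = find_anchors(emb_ref, emb_meas, k=anchor_k)
    if len(anchors) == 0:
        raise ValueError("no mutual-nearest-neighbor anchors found")
    ref_pcs, meas_pcs = _joint_pca(ref_z, meas_z, pca_dims, seed)
    out = {}
    for kind, labels in ref_labels_by_kind.items():
        anchor_labels = np.asarray(labels, dtype=object)[anchors.ref_idx]
        out[kind] = transfer_labels(
            ref_pcs[anchors.ref_idx], anchor_labels, meas_pcs, transfer_k
        )
    return out, anchors, ref_pcs, meas_pcs


def two_round_transfer(
    ref: ReferenceDataset,
    meas: CellTable,
    n_parts: int | None = None,
    cca_dims: int = 100,
    pca_dims: int = 100,
    anchor_k: int = 5,
    transfer_k: int = 100,
    downsample: int = 100_000,
    subclass_gate: float = 0.8,
    cluster_gate: float = 0.5,
    seed: int = 0,
) -> TransferResult:
    """Two-round label transfer from reference to measured cells.

    Round 1 transfers integration-partition labels on the measurement
    panel genes; round 2 runs per partition on that partition's positive-
    log-dispersion genes, transferring subclass and cluster labels.
    Final subclass/cluster confidences are the round-2 confidence times
    the partition confidence.
    """
    shared = [g for g in meas.genes if g in set(ref.genes)]
    ref_gi = {g: j for j, g in enumerate(ref.genes)}
    meas_gi = {g: j for j, g in enumerate(meas.genes)}
    ref_panel = ref.counts[:, [ref_gi[g] for g in shared]]
    meas_panel = meas.counts[:, [meas_gi[g] for g in shared]]

    if ref.partition_labels is None:
        build_partitions(ref, n_parts=n_parts, pca_dims=pca_dims, seed=seed)
    parts = np.asarray(ref.partition_labels)

    round1, _, _, _ = _one_round(
        ref_panel,
        meas_panel,
        {"partition": parts},
        cca_dims,
        pca_dims,
        anchor_k,
        transfer_k,
        downsample,
        seed,
    )
    part_labels, part_conf = round1["partition"]

    n = meas.n_cells
    sub_lab = np.empty(n, dtype=object)
    clu_lab = np.empty(n, dtype=object)
    sub_conf = np.zeros(n)
    clu_conf = np.zeros(n)
    for p in sorted(set(int(v) for v in parts)):
        meas_mask = np.array([lab == p for lab in part_labels])
        if not meas_mask.any():
            logger.warning("two_round_transfer: no measured cells in partition %d", p)
            continue
        ref_mask = parts == p
        hv = positive_dispersion_genes(
            ref.counts[ref_mask][:, [ref_gi[g] for g in shared]], shared
        )
        if len(hv) < 2:
            hv = shared
        cols = [shared.index(g) for g in hv]
        r_counts = ref_panel[ref_mask][:, cols]
        m_counts = meas_panel[meas_mask][:, cols]
        keep = m_counts.sum(axis=1) > 0
        meas_pos = np.flatnonzero(meas_mask)[keep]
        if len(meas_pos) == 0:
            continue
        res, _, _, _ = _one_round(
            r_counts,
            m_counts[keep],
            {
                "subclass": ref.subclass_labels[ref_mask],
                "cluster": ref.cluster_labels[ref_mask],
            },
            cca_dims,
            pca_dims,
            anchor_k,
            transfer_k,
            downsample,
            seed + 1 + p,
        )
        sub_lab[meas_pos], sub_conf[meas_pos] = res["subclass"]
        clu_lab[meas_pos], clu_conf[meas_pos] = res["cluster"]

    sub_adj = sub_conf * part_conf
    clu_adj = clu_conf * part_conf
    table = pd.DataFrame(
        {
            "partition_label": [int(v) if v is not None else -1 for v in part_labels],
            "partition_confidence": part_conf,
            "subclass_label": sub_lab,
            "subclass_confidence": sub_adj,
            "subclass_pass": sub_adj > subclass_gate,
            "cluster_label": clu_lab,
            "cluster_confidence": clu_adj,
            "cluster_pass": clu_adj > cluster_gate,
        },
        index=meas.cell_ids,
    )
    return TransferResult(table=table)


# ---------------------------------------------------------------------------
# imputation and the cosine-mapping cross-check


def impute(
    meas: CellTable,
    ref: ReferenceDataset,
    anchor_k: int = 5,
    impute_k: int = 30,
    cca_dims: int = 100,
    pca_dims: int = 100,
    downsample: int = 100_000,
    seed: int = 0,
) -> CellTable:
    """Impute full-transcriptome profiles for measured cells.

    Each measured cell's profile is a weighted average of the reference
    log-normalized expression of its ``impute_k`` nearest anchor
    reference-cells in the joint PCA space.  Weights are a Gaussian
    kernel of the distances with adaptive bandwidth equal to the distance
    to the ``impute_k``-th anchor, normalized to sum to one.
    """
    shared = [g for g in meas.genes if g in set(ref.genes)]
    ref_gi = {g: j for j, g in enumerate(ref.genes)}
    meas_gi = {g: j for j, g in enumerate(meas.genes)}
    ref_z = standardize(ref.counts[:, [ref_gi[g] for g in shared]])
    meas_z = standardize(meas.counts[:, [meas_gi[g] for g in shared]])
    dims = min(cca_dims, len(shared), ref_z.shape[0], meas_z.shape[0])
    emb_ref, emb_meas = cca_coembed(ref_z, meas_z, dims, downsample, seed)
    anchors = find_anchors(emb_ref, emb_meas, k=anchor_k)
    if len(anchors) == 0:
        raise ValueError("no anchors; cannot impute")
    ref_pcs, meas_pcs = _joint_pca(ref_z, meas_z, pca_dims, seed)
    anchor_refs = np.unique(anchors.ref_idx)
    k = min(impute_k, len(anchor_refs))
    if k < impute_k:
        logger.warning("impute: only %d anchor reference cells available", k)
    nn = NearestNeighbors(n_neighbors=k).fit(ref_pcs[anchor_refs])
    dist, nbrs = nn.kneighbors(meas_pcs)
    ref_expr = lognormalize(ref.counts)
    bandwidth = dist[:, -1:].copy()
    bandwidth[bandwidth == 0] = 1.0
    w = np.exp(-((dist / bandwidth) ** 2))
    w /= w.sum(axis=1, keepdims=True)
    imputed = np.einsum("ik,ikg->ig", w, ref_expr[anchor_refs[nbrs]])
    out = meas.subset(np.arange(meas.n_cells))
    out.imputed = imputed
    out.imputed_genes = list(ref.genes)
    return out


def cosine_assign(
    meas_expr: np.ndarray, cluster_profiles: dict
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each cell to the cluster with minimum cosine distance.

    ``cluster_profiles`` maps cluster label to a mean expression vector
    over the same genes as ``meas_expr`` columns.  Zero-expression cells
    are returned unassigned (None label).
    Returns (labels, cosine distances).
    """
    names = sorted(cluster_profiles)
    profiles = np.vstack([cluster_profiles[c] for c in names]).astype(float)
    pn = np.linalg.norm(profiles, axis=1)
    if np.any(pn == 0):
        raise ValueError("zero-vector cluster profile")
    x = np.asarray(meas_expr, dtype=float)
    xn = np.linalg.norm(x, axis=1)
    labels = np.empty(len(x), dtype=object)
    dists = np.full(len(x), np.nan)
    ok = xn > 0
    if ok.any():
        cos = (x[ok] @ profiles.T) / (xn[ok, None] * pn[None, :])
        best = np.argmax(cos, axis=1)
        labels[np.flatnonzero(ok)] = [names[b] for b in best]
        dists[np.flatnonzero(ok)] = 1 - cos[np.arange(ok.sum()), best]
    return labels, dists
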