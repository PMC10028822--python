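"""Spatial-proximity cell-cell interaction calling and ligand-receptor
upregulation in proximal cell pairs.

Two cells form a proximal pair when their soma centroids lie strictly
within a radius R (15 um, about one soma diameter, in strict mode; 30 um
in relaxed mode to admit paracrine-range signalling).  The null keeps
every cell's local environment: each cell is displaced uniformly within
a 100 um disk, proximal pairs are recounted, and over many rounds the
counts are fitted by a normal distribution.  A type pair is called
interacting when the observed count clears the Benjamini-Hochberg
adjusted upper-tail p-value threshold and a minimum observed-pair count;
relaxed-mode calls additionally require at least one ligand-receptor
pair upregulated in the proximal cell pairs.

The ligand-receptor score for cells (i, j) and a multi-subunit pair is
S = ln(1 + prod_p L_p(i) * prod_q R_q(j)); proximal-pair scores are
compared with an equal-size sample of non-proximal pairs by a one-sided
Welch t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm, ttest_ind
from statsmodels.stats.multitest import multipletests

from .core_io import CellTable, LRDatabase
from .integration import positive_dispersion_genes
from .region_stats import EnrichmentMatrix

logger = logging.getLogger("brainatlas")

__all__ = [
    "ProximityParams",
    "eligible_types",
    "count_proximal",
    "randomization_null",
    "test_interactions",
    "lr_score",
    "lr_test",
    "upregulated_genes",
    "call_pipeline",
]


@dataclass(frozen=True)
class ProximityParams:
    r_proximal: float = 15.0  # um
    r_randomization: float = 100.0  # um
    n_rounds: int = 1000
    alpha: float = 0.05
    min_observed_pairs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_proximal >= self.r_randomization:
            raise ValueError("r_proximal must be below r_randomization")
        if self.n_rounds < 2:
            raise ValueError("n_rounds must be >= 2")


def eligible_types(
    cells: CellTable,
    region: str,
    enrichment: EnrichmentMatrix,
    category_of: dict,
    high_threshold_regions: set = frozenset(),
    confidence_gate: float = 0.8,
    min_other_count: int = 50,
) -> tuple[list, CellTable]:
    """Types admitted to interaction analysis in one region.

    Cells are first gated at subclass label-transfer confidence > 0.8.
    Neuronal types need enrichment >= 6 in the high-complexity regions
    (subdivided hypothalamus/midbrain/hindbrain) and >= 2 elsewhere;
    astrocytes need >= 1; remaining non-neuronal types need more than
    ``min_other_count`` cells in the region.  Returns (types, gated
    region cells).
    """
    conf = cells.meta.get("subclass_confidence")
    gate = np.ones(cells.n_cells, bool) if conf is None else conf.to_numpy() > confidence_gate
    in_region = (cells.meta["region_label"] == region).to_numpy()
    sub = cells.subset(gate & in_region)
    counts = sub.meta["subclass_label"].value_counts()
    neuron_thresh = 6.0 if region in high_threshold_regions else 2.0
    out = []
    for t in sorted(counts.index):
        cat = category_of.get(t, "other")
        score = (
            float(enrichment.scores.loc[t, region])
            if t in enrichment.scores.index and region in enrichment.scores.columns
            else 0.0
        )
        if cat == "neuronal":
            ok = score >= neuron_thresh
        elif cat == "astrocyte":
            ok = score >= 1.0
        else:
            ok = counts[t] > min_other_count
        if ok:
            out.append(t)
    return out, sub


def _strict_radius(r: float) -> float:
    # count_neighbors uses <=; the largest float below r makes it strict
    return np.nextafter(r, 0.0)


def count_proximal(
    xy_a: np.ndarray,
    xy_b: np.ndarray,
    r: float,
    same_set: bool = False,
    section_a: np.ndarray | None = None,
    section_b: np.ndarray | None = None,
) -> int:
    """Number of unordered proximal pairs (distance strictly below r).

    With ``same_set`` the two inputs are the same cells and each
    unordered pair is counted once.  Sections, if given, are handled
    independently and summed (pairs never span sections).
    """
    xy_a = np.asarray(xy_a, dtype=float)
    xy_b = np.asarray(xy_b, dtype=float)
    if section_a is not None:
        total = 0
        section_a = np.asarray(section_a)
        section_b = np.asarray(section_b)
        for sec in np.unique(section_a):
            total += count_proximal(
                xy_a[section_a == sec], xy_b[section_b == sec], r, same_set
            )
        return total
    if len(xy_a) == 0 or len(xy_b) == 0:
        return 0
    rr = _strict_radius(r)
    tree_a = cKDTree(xy_a)
    tree_b = cKDTree(xy_b)
    n = int(tree_a.count_neighbors(tree_b, rr))
    if same_set:
        return (n - len(xy_a)) // 2
    return n


def _displace(
    rng: np.random.Generator,
    xy: np.ndarray,
    radius: float,
    bounds: tuple | None = None,
) -> np.ndarray:
    """Uniform in-plane displacement within a disk of ``radius``.

    When ``bounds`` (x0, y0, x1, y1) is given, displaced positions are
    reflected back into the window.  Without reflection, cells near the
    section edge would leak outside the imaged area and the null would
    systematically undercount proximal pairs (an edge effect that
    inflates the type-I error under complete spatial randomness).
    Reflection preserves a uniform density and keeps every displaced
    position within ``radius`` of its origin for windows wider than
    2 x radius.
    """
    n = len(xy)
    rad = radius * np.sqrt(rng.uniform(size=n))
    ang = rng.uniform(0, 2 * np.pi, n)
    out = xy + np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    if bounds is not None:
        x0, y0, x1, y1 = bounds
        for dim, lo, hi in ((0, x0, x1), (1, y0, y1)):
            v = out[:, dim]
            v = np.where(v < lo, 2 * lo - v, v)
            v = np.where(v > hi, 2 * hi - v, v)
            out[:, dim] = np.clip(v, lo, hi)
    return out


def _bounds_of(xy: np.ndarray) -> tuple:
    return (
        float(xy[:, 0].min()),
        float(xy[:, 1].min()),
        float(xy[:, 0].max()),
        float(xy[:, 1].max()),
    )


def randomization_null(
    xy_a: np.ndarray,
    xy_b: np.ndarray,
    params: ProximityParams = ProximityParams(),
    same_set: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, np.ndarray]:
    """Local-randomization null for one type pair.

    Per round, every cell moves to a uniform random position within
    ``r_randomization`` of its original location (in plane); proximal
    pairs are recounted.  Returns the fitted normal (mean, sd, samples);
    sd is floored at 1e-9.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    bounds = _bounds_of(np.vstack([xy_a, xy_b]))
    samples = np.empty(params.n_rounds)
    for t in range(params.n_rounds):
        a = _displace(rng, xy_a, params.r_randomization, bounds)
        b = a if same_set else _displace(rng, xy_b, params.r_randomization, bounds)
        samples[t] = count_proximal(a, b, params.r_proximal, same_set)
    mu = float(samples.mean())
    sd = max(float(samples.std(ddof=1)), 1e-9)
    return mu, sd, samples


def test_interactions(
    cells_region: CellTable,
    types: list,
    params: ProximityParams = ProximityParams(),
    mode: str = "strict15",
) -> pd.DataFrame:
    """Test every type pair in a region against the randomization null.

    All cells of the listed types are displaced together each round, so
    one set of randomizations serves every pair (the per-round positions
    are shared, exactly as local densities are shared).  The upper-tail
    p-value is the larger of the fitted-normal tail and the empirical
    randomization tail (the normal fit alone has slightly light tails on
    discrete counts), floored at 1/(n_rounds + 1), and BH-adjusted
    across the pairs of the region.  Self pairs are computed and
    flagged.
    """
    sub_labels = cells_region.meta["subclass_label"].to_numpy(dtype=object)
    sections = cells_region.meta["section_id"].to_numpy()
    xy = cells_region.meta[["x", "y"]].to_numpy()
    idx_of = {t: np.flatnonzero(sub_labels == t) for t in types}
    pairs = [
        (a, b) for i, a in enumerate(sorted(types)) for b in sorted(types)[i:]
    ]
    pairs = [(a, b) for a, b in pairs if len(idx_of[a]) and len(idx_of[b])]
    if not pairs:
        return pd.DataFrame(
            columns=[
                "type_a", "type_b", "observed", "null_mean", "null_sd",
                "fold", "p_raw", "p_adj", "called", "is_self", "mode",
            ]
        )

    def counts_at(positions):
        out = {}
        for a, b in pairs:
            ia, ib = idx_of[a], idx_of[b]
            out[(a, b)] = count_proximal(
                positions[ia],
                positions[ib],
                params.r_proximal,
                same_set=a == b,
                section_a=sections[ia],
                section_b=sections[ib],
            )
        return out

    observed = counts_at(xy)
    rng = np.random.default_rng(params.seed)
    sec_bounds = {
        sec: _bounds_of(xy[sections == sec]) for sec in np.unique(sections)
    }
    samples = {p: np.empty(params.n_rounds) for p in pairs}
    for t in range(params.n_rounds):
        shifted = xy.copy()
        for sec, b in sec_bounds.items():
            m = sections == sec
            shifted[m] = _displace(rng, xy[m], params.r_randomization, b)
        for p, c in counts_at(shifted).items():
            samples[p][t] = c

    rows = []
    p_floor = 1.0 / (params.n_rounds + 1)
    for a, b in pairs:
        s = samples[(a, b)]
        mu = float(s.mean())
        sd = max(float(s.std(ddof=1)), 1e-9)
        obs = observed[(a, b)]
        p_norm = float(norm.sf(obs, mu, sd))
        p_emp = (1 + int((s >= obs).sum())) / (params.n_rounds + 1)
        p_raw = min(max(p_norm, p_emp, p_floor), 1.0)
        fold = obs / mu if mu > 0 else (math.inf if obs > 0 else 0.0)
        rows.append(
            {
                "type_a": a, "type_b": b, "observed": obs,
                "null_mean": mu, "null_sd": sd, "fold": fold,
                "p_raw": p_raw, "is_self": a == b, "mode": mode,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    df["called"] = (df["p_adj"] < params.alpha) & (
        df["observed"] >= params.min_observed_pairs
    )
    return df


# ---------------------------------------------------------------------------
# ligand-receptor scoring


def lr_score(
    ligand_expr: np.ndarray, receptor_expr: np.ndarray, literal: bool = False
) -> np.ndarray:
    """Ligand-receptor expression score S = ln(1 + prod(L) * prod(R)).

    ``ligand_expr``/``receptor_expr`` carry one column per subunit (cells
    or cell pairs as rows).  ``literal`` switches to the all-cross-terms
    product prod_{p,q} L_p R_q = (prod L)^|q| * (prod R)^|p|.
    """
    lig = np.atleast_2d(np.asarray(ligand_expr, dtype=float))
    rec = np.atleast_2d(np.asarray(receptor_expr, dtype=float))
    pl = lig.prod(axis=1)
    pr = rec.prod(axis=1)
    if literal:
        inner = pl ** rec.shape[1] * pr ** lig.shape[1]
    else:
        inner = pl * pr
    return np.log1p(inner)


def _pair_set_expression(cells: CellTable, genes: tuple) -> np.ndarray | None:
    """Per-cell expression for the listed genes, preferring imputed values."""
    if cells.imputed is not None and cells.imputed_genes is not None:
        gi = {g: j for j, g in enumerate(cells.imputed_genes)}
        if all(g in gi for g in genes):
            return cells.imputed[:, [gi[g] for g in genes]]
    gi = {g: j for j, g in enumerate(cells.genes)}
    if all(g in gi for g in genes):
        return cells.expression()[:, [gi[g] for g in genes]]
    return None


def _proximal_pairs(
    cells_a: CellTable, cells_b: CellTable, r: float
) -> list[tuple[int, int]]:
    xy_a = cells_a.meta[["x", "y"]].to_numpy()
    xy_b = cells_b.meta[["x", "y"]].to_numpy()
    sec_a = cells_a.meta["section_id"].to_numpy()
    sec_b = cells_b.meta["section_id"].to_numpy()
    rr = _strict_radius(r)
    pairs = []
    for sec in np.unique(sec_a):
        ia = np.flatnonzero(sec_a == sec)
        ib = np.flatnonzero(sec_b == sec)
        if not len(ia) or not len(ib):
            continue
        tree_b = cKDTree(xy_b[ib])
        for i, nbrs in zip(ia, cKDTree(xy_a[ia]).query_ball_tree(tree_b, rr)):
            pairs.extend((i, ib[j]) for j in nbrs)
    return pairs


def _sample_nonproximal(
    cells_a: CellTable,
    cells_b: CellTable,
    proximal: set,
    n: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Seeded sample (without replacement) of pairs at distance > r.

    Rejection sampling against the proximal set; falls back to exhaustive
    enumeration when pairs are scarce.
    """
    na, nb = cells_a.n_cells, cells_b.n_cells
    total = na * nb
    avail = total - len(proximal)
    if avail <= n:
        all_pairs = [
            (i, j) for i in range(na) for j in range(nb) if (i, j) not in proximal
        ]
        logger.warning("fewer non-proximal than proximal pairs; using all %d", len(all_pairs))
        return all_pairs
    chosen: set = set()
    while len(chosen) < n:
        i = int(rng.integers(na))
        j = int(rng.integers(nb))
        if (i, j) not in proximal and (i, j) not in chosen:
            chosen.add((i, j))
    return sorted(chosen)


def lr_test(
    cells_a: CellTable,
    cells_b: CellTable,
    lrdb: LRDatabase,
    r_proximal: float = 30.0,
    min_fold: float = 2.0,
    max_p: float = 0.01,
    min_frac_positive: float = 0.4,
    seed: int = 0,
    literal: bool = False,
) -> pd.DataFrame:
    """Test each ligand-receptor pair for upregulation in proximal pairs.

    Scores over all proximal (A, B) cell pairs are compared with an
    equal-size seeded sample of non-proximal pairs by a one-sided Welch
    t-test; p-values are BH-adjusted across the database.  Significance
    requires mean fold >= ``min_fold``, adjusted p < ``max_p``, and a
    positive score in at least ``min_frac_positive`` of proximal pairs.
    """
    prox = _proximal_pairs(cells_a, cells_b, r_proximal)
    if len(prox) < 2:
        raise ValueError("need at least 2 proximal pairs")
    rng = np.random.default_rng(seed)
    nonprox = _sample_nonproximal(cells_a, cells_b, set(prox), len(prox), rng)
    rows = []
    for pair in lrdb.pairs:
        lig = _pair_set_expression(cells_a, pair.ligand_subunits)
        rec = _pair_set_expression(cells_b, pair.receptor_subunits)
        if lig is None or rec is None:
            logger.warning("lr_test: missing subunit genes for %s; skipped", pair.pair_id)
            continue
        ai = np.array([p[0] for p in prox])
        bi = np.array([p[1] for p in prox])
        s_prox = lr_score(lig[ai], rec[bi], literal)
        ai = np.array([p[0] for p in nonprox])
        bi = np.array([p[1] for p in nonprox])
        s_non = lr_score(lig[ai], rec[bi], literal)
        mean_p, mean_n = float(s_prox.mean()), float(s_non.mean())
        fold = mean_p / mean_n if mean_n > 0 else (math.inf if mean_p > 0 else 1.0)
        if np.std(s_prox) == 0 and np.std(s_non) == 0:
            p_raw = 1.0 if mean_p <= mean_n else 0.0
        else:
            p_raw = float(
                ttest_ind(s_prox, s_non, equal_var=False, alternative="greater").pvalue
            )
        rows.append(
            {
                "pair_id": pair.pair_id,
                "pathway": pair.pathway,
                "mean_proximal": mean_p,
                "mean_nonproximal": mean_n,
                "fold": fold,
                "p_raw": p_raw,
                "frac_positive_proximal": float((s_prox > 0).mean()),
                "n_proximal": len(prox),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
        df["significant"] = (
            (df["fold"] >= min_fold)
            & (df["p_adj"] < max_p)
            & (df["frac_positive_proximal"] >= min_frac_positive)
        )
    return df


def upregulated_genes(
    cells_a: CellTable,
    cells_b: CellTable,
    r_proximal: float = 30.0,
    hvgs: list | None = None,
    min_fold: float = 2.0,
    max_p: float = 0.01,
) -> pd.DataFrame:
    """Genes upregulated in type-A cells proximal to any type-B cell.

    Type-A cells split into proximal/non-proximal groups by whether any
    type-B cell lies within ``r_proximal``; one-sided Welch t-tests with
    BH adjustment over the highly variable genes of type A (positive
    log-dispersion by default) yield genes with fold >= ``min_fold`` and
    adjusted p < ``max_p``.
    """
    if hvgs is None:
        hvgs = positive_dispersion_genes(cells_a.counts, cells_a.genes)
    prox_idx = {i for i, _ in _proximal_pairs(cells_a, cells_b, r_proximal)}
    is_prox = np.array([i in prox_idx for i in range(cells_a.n_cells)])
    if not is_prox.any() or is_prox.all():
        logger.warning("upregulated_genes: one group empty")
        return pd.DataFrame(columns=["gene", "fold", "p_raw", "p_adj"])
    expr = cells_a.expression()
    gi = {g: j for j, g in enumerate(cells_a.genes)}
    rows = []
    for g in hvgs:
        if g not in gi:
            continue
        x = expr[is_prox, gi[g]]
        y = expr[~is_prox, gi[g]]
        mean_x, mean_y = float(x.mean()), float(y.mean())
        fold = mean_x / mean_y if mean_y > 0 else (math.inf if mean_x > 0 else 1.0)
        if np.std(x) == 0 and np.std(y) == 0:
            p = 1.0 if mean_x <= mean_y else 0.0
        else:
            p = float(ttest_ind(x, y, equal_var=False, alternative="greater").pvalue)
        rows.append({"gene": g, "fold": fold, "p_raw": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
        df = df[(df["fold"] >= min_fold) & (df["p_adj"] < max_p)].reset_index(drop=True)
    return df


def call_pipeline(
    cells: CellTable,
    types_by_region: dict,
    lrdb: LRDatabase | None = None,
    params: ProximityParams = ProximityParams(),
    r_relaxed: float = 30.0,
    lr_min_fold: float = 2.0,
    lr_max_p: float = 0.01,
    lr_min_frac_positive: float = 0.4,
) -> dict:
    """Run strict (15 um) and relaxed (30 um) interaction calling.

    ``types_by_region`` maps region label to the eligible type list.
    Relaxed-mode calls require at least one significant ligand-receptor
    pair; the merged call set is deduplicated (a pair called in both
    modes appears once, strict taking precedence).  Returns dict with
    'interactions', 'lr_hits', and 'calls' tables.
    """
    inter_rows, lr_rows, calls = [], [], {}
    for region, types in types_by_region.items():
        region_cells = cells.subset(
            (cells.meta["region_label"] == region).to_numpy()
        )
        strict = test_interactions(region_cells, types, params, mode="strict15")
        strict["region"] = region
        inter_rows.append(strict)
        for _, row in strict[strict["called"]].iterrows():
            calls.setdefault((region, row["type_a"], row["type_b"]), "strict15")
        relaxed_params = ProximityParams(
            r_proximal=r_relaxed,
            r_randomization=params.r_randomization,
            n_rounds=params.n_rounds,
            alpha=params.alpha,
            min_observed_pairs=params.min_observed_pairs,
            seed=params.seed + 1,
        )
        relaxed = test_interactions(region_cells, types, relaxed_params, mode="relaxed30")
        relaxed["region"] = region
        inter_rows.append(relaxed)
        if lrdb is None:
            continue
        for _, row in relaxed[relaxed["called"]].iterrows():
            a, b = row["type_a"], row["type_b"]
            cells_a = region_cells.subset(
                (region_cells.meta["subclass_label"] == a).to_numpy()
            )
            cells_b = region_cells.subset(
                (region_cells.meta["subclass_label"] == b).to_numpy()
            )
            try:
                lr = lr_test(
                    cells_a,
                    cells_b,
                    lrdb,
                    r_proximal=r_relaxed,
                    min_fold=lr_min_fold,
                    max_p=lr_max_p,
                    min_frac_positive=lr_min_frac_positive,
                    seed=params.seed,
                )
            except ValueError:
                continue
            lr["region"], lr["type_a"], lr["type_b"] = region, a, b
            lr_rows.append(lr)
            if len(lr) and lr["significant"].any():
                calls.setdefault((region, a, b), "relaxed30")
    interactions = (
        pd.concat(inter_rows, ignore_index=True) if inter_rows else pd.DataFrame()
    )
    lr_hits = pd.concat(lr_rows, ignore_index=True) if lr_rows else pd.DataFrame()
    call_df = pd.DataFrame(
        [
            {"region": r, "type_a": a, "type_b": b, "mode": m}
            for (r, a, b), m in sorted(calls.items())
        ]
    )
    return {"interactions": interactions, "lr_hits": lr_hits, "calls": call_df}
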