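"""Gene-panel selection, error-robust barcode codebooks and probe targets.

The codebook is a binary constant-weight code: every barcode has Hamming
weight 4 and every pair of barcodes is at Hamming distance >= 4.  Two
weight-4 words are at distance >= 4 exactly when they share at most two
set bits, so a maximal codebook is a Steiner quadruple system SQS(n): a
family of 4-subsets of the n bit positions covering every 3-subset
exactly once, of size C(n,3)/4.  ``construct_codebook`` builds SQS(n)
for n a power of two by the classical doubling recursion, which attains
the maximum (1240 barcodes at n = 32).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .core_io import Codebook, CodebookEntry, ReferenceDataset

__all__ = [
    "DECriteria",
    "ProbeParams",
    "GenePanel",
    "CodebookReport",
    "CodeSize",
    "de_genes",
    "trim_pool",
    "assemble_panel",
    "validate_codebook",
    "max_code_size",
    "construct_codebook",
    "assign_barcodes",
    "design_target_regions",
    "build_kmer_index",
    "TargetRegionResult",
]


# ---------------------------------------------------------------------------
# differential expression and panel assembly


@dataclass(frozen=True)
class DECriteria:
    """Selection thresholds for pairwise differential-expression screening."""

    min_fold: float = 2.0
    max_p: float = 0.01
    min_fg_expr_frac: float = 0.5
    min_frac_enrichment: float = 3.3
    top_n: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.min_fg_expr_frac <= 1:
            raise ValueError("min_fg_expr_frac must lie in (0, 1]")
        if min(self.min_fold, self.max_p, self.min_frac_enrichment, self.top_n) <= 0:
            raise ValueError("criteria must be positive")


def _normalize_totals(counts: np.ndarray, target: float = 1000.0) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    return counts / totals * target


def de_genes(
    ref: ReferenceDataset,
    cluster_a,
    cluster_b,
    criteria: DECriteria = DECriteria(),
) -> tuple[list[str], list[str]]:
    """Screen genes differentially expressed between two reference clusters.

    A gene enters the foreground-up list when its normalized-mean fold
    change is >= ``min_fold``, the two-sided Wilcoxon rank-sum p-value is
    < ``max_p``, at least ``min_fg_expr_frac`` of foreground cells express
    it (count > 0), and its expressing fraction exceeds the background's
    by more than ``min_frac_enrichment``-fold.  Each direction is ranked
    by ascending p-value and truncated to ``top_n``.
    Returns (a-up, b-up).
    """
    for c in (cluster_a, cluster_b):
        if c not in set(ref.cluster_labels):
            raise ValueError(f"unknown cluster label: {c}")
    mask_a = ref.cluster_labels == cluster_a
    mask_b = ref.cluster_labels == cluster_b
    norm = _normalize_totals(ref.counts)
    xa, xb = norm[mask_a], norm[mask_b]
    raw_a, raw_b = ref.counts[mask_a], ref.counts[mask_b]
    mean_a, mean_b = xa.mean(axis=0), xb.mean(axis=0)
    frac_a = (raw_a > 0).mean(axis=0)
    frac_b = (raw_b > 0).mean(axis=0)

    def _direction(mean_fg, mean_bg, frac_fg, frac_bg, fg, bg):
        hits = []
        for j, gene in enumerate(ref.genes):
            if mean_fg[j] == 0:
                continue
            fold = math.inf if mean_bg[j] == 0 else mean_fg[j] / mean_bg[j]
            if fold < criteria.min_fold:
                continue
            if frac_fg[j] < criteria.min_fg_expr_frac:
                continue
            enr = math.inf if frac_bg[j] == 0 else frac_fg[j] / frac_bg[j]
            if not enr > criteria.min_frac_enrichment:
                continue
            if np.all(fg[:, j] == fg[0, j]) and np.all(bg[:, j] == fg[0, j]):
                continue  # identical constant samples: no evidence
            p = mannwhitneyu(fg[:, j], bg[:, j], alternative="two-sided").pvalue
            if p < criteria.max_p:
                hits.append((p, gene))
        hits.sort(key=lambda t: (t[0], t[1]))
        return [g for _, g in hits[: criteria.top_n]]

    a_up = _direction(mean_a, mean_b, frac_a, frac_b, xa, xb)
    b_up = _direction(mean_b, mean_a, frac_b, frac_a, xb, xa)
    return a_up, b_up


def trim_pool(
    genes: list[str],
    probe_capacity: dict,
    cluster_max_mean: dict,
    min_capacity: int = 40,
    max_mean: float = 3000.0,
) -> list[str]:
    """Drop genes too short or too abundant for imaging.

    Genes accommodating fewer than ``min_capacity`` hybridization probes,
    or expressed above ``max_mean`` mean counts in their highest-expressing
    cluster, are removed (both comparisons strict).
    """
    missing = [g for g in genes if g not in probe_capacity or g not in cluster_max_mean]
    if missing:
        raise KeyError(f"maps do not cover genes: {missing[:5]}")
    return [
        g
        for g in genes
        if not (probe_capacity[g] < min_capacity or cluster_max_mean[g] > max_mean)
    ]


@dataclass
class GenePanel:
    genes: list[str]
    curated: list[str]
    uncovered: list[tuple] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)


def assemble_panel(
    curated: list[str],
    de_pool: dict,
    min_cover: int = 3,
) -> GenePanel:
    """Greedy panel assembly from curated genes plus DE candidates.

    ``de_pool`` maps directional cluster pairs ``(foreground, background)``
    to p-ranked gene lists.  Starting from the curated set, the direction
    with the worst current coverage is topped up with its best-ranked
    not-yet-included gene, until every direction has at least ``min_cover``
    panel genes or its pool is exhausted.  Exhausted directions are
    reported, not raised.
    """
    panel = list(dict.fromkeys(curated))
    in_panel = set(panel)
    coverage = {
        key: sum(g in in_panel for g in pool) for key, pool in de_pool.items()
    }
    exhausted: set = set()
    while True:
        open_dirs = [
            k
            for k in de_pool
            if coverage[k] < min_cover and k not in exhausted
        ]
        if not open_dirs:
            break
        key = min(open_dirs, key=lambda k: (coverage[k], k))
        gene = next((g for g in de_pool[key] if g not in in_panel), None)
        if gene is None:
            exhausted.add(key)
            continue
        panel.append(gene)
        in_panel.add(gene)
        for k, pool in de_pool.items():
            if gene in pool:
                coverage[k] += 1
    uncovered = sorted(k for k in de_pool if coverage[k] < min_cover)
    return GenePanel(genes=panel, curated=list(curated), uncovered=uncovered)


# ---------------------------------------------------------------------------
# codebook construction and validation


@dataclass
class CodebookReport:
    weights: list[int]
    min_distance: int | None
    n_duplicates: int
    passed: bool


def validate_codebook(
    cb: Codebook, weight: int = 4, min_distance: int = 4
) -> CodebookReport:
    """Exhaustively check constant weight and minimum pairwise distance."""
    mat = cb.barcode_matrix().astype(np.int32)
    weights = mat.sum(axis=1).tolist()
    n = mat.shape[0]
    n_dup = n - len({tuple(r) for r in mat})
    if n < 2:
        dmin = None
    else:
        # pairwise Hamming distance for 0/1 rows
        overlap = mat @ mat.T
        w = mat.sum(axis=1)
        dist = w[:, None] + w[None, :] - 2 * overlap
        iu = np.triu_indices(n, k=1)
        dmin = int(dist[iu].min())
    passed = (
        all(w == weight for w in weights)
        and n_dup == 0
        and (dmin is None or dmin >= min_distance)
    )
    return CodebookReport(
        weights=weights, min_distance=dmin, n_duplicates=n_dup, passed=passed
    )


class CodeSize(int):
    """Integer code size carrying an ``exact`` flag (False = bound only)."""

    exact: bool

    def __new__(cls, value: int, exact: bool):
        obj = super().__new__(cls, value)
        obj.exact = exact
        return obj


def _packing_bound(n_bits: int, weight: int) -> int:
    # distance-4 constant-weight words pairwise share <= weight-2 bits,
    # i.e. every (weight-1)-subset of positions lies in at most one word
    return math.comb(n_bits, weight - 1) // weight


def _exhaustive_max(n_bits: int, weight: int = 4, min_distance: int = 4) -> int:
    """Branch-and-bound maximum code size over all weight-w words.

    Candidates are kept as words compatible (distance >= min_distance)
    with the current code; the triple-packing bound prunes branches that
    cannot beat the incumbent.
    """
    words = [frozenset(c) for c in itertools.combinations(range(n_bits), weight)]
    max_overlap = weight - min_distance // 2
    compat = [
        {j for j, w2 in enumerate(words) if j != i and len(w1 & w2) <= max_overlap}
        for i, w1 in enumerate(words)
    ]
    total_triples = math.comb(n_bits, weight - 1)
    best = 0

    def recurse(chosen: int, cands: list[int]) -> None:
        nonlocal best
        if chosen > best:
            best = chosen
        # packing bound: each chosen word consumes comb(w, w-1)=w fresh triples
        bound = min(len(cands), (total_triples - weight * chosen) // weight)
        if chosen + bound <= best or not cands:
            return
        for pos, i in enumerate(cands):
            # words skipped at this level are excluded from deeper branches
            rest = [j for j in cands[pos + 1 :] if j in compat[i]]
            if chosen + 1 + min(len(rest), (total_triples - weight * (chosen + 1)) // weight) > best:
                recurse(chosen + 1, rest)
        return

    recurse(0, list(range(len(words))))
    return best


def max_code_size(
    n_bits: int, weight: int = 4, min_distance: int = 4, exhaustive: bool = False
) -> CodeSize:
    """Maximum size of a constant-weight binary code.

    For weight 4 and distance 4 with ``n_bits`` congruent to 2 or 4 mod 6
    this is the Steiner quadruple packing number C(n,3)/4 (exact);
    other parameter combinations return the packing bound flagged as
    bound-only.  ``exhaustive`` additionally verifies small instances
    (n_bits <= 10) by branch-and-bound search.
    """
    if weight == 4 and min_distance == 4 and n_bits % 6 in (2, 4):
        size = math.comb(n_bits, 3) // 4
        if exhaustive:
            if n_bits > 10:
                raise ValueError("exhaustive search supported only for n_bits <= 10")
            found = _exhaustive_max(n_bits, weight, min_distance)
            if found != size:
                raise AssertionError(
                    f"exhaustive search found {found}, formula gives {size}"
                )
        return CodeSize(size, exact=True)
    return CodeSize(_packing_bound(n_bits, weight), exact=False)


def _one_factorization(n: int) -> list[list[tuple[int, int]]]:
    """Round-robin one-factorization of the complete graph on n points."""
    if n % 2:
        raise ValueError("n must be even")
    factors = []
    m = n - 1
    for r in range(m):
        factor = [(m, r)]
        for i in range(1, n // 2):
            factor.append(((r + i) % m, (r - i) % m))
        factors.append([tuple(sorted(e)) for e in factor])
    return factors


def _double_sqs(blocks: list[frozenset], n: int) -> list[frozenset]:
    """SQS(2n) from SQS(n): doubled blocks in each point copy plus cross
    blocks {a0, b0, c1, d1} with {a,b} and {c,d} edges of the same
    one-factor of a round-robin one-factorization of K_n."""
    out: list[frozenset] = []
    for b in blocks:
        out.append(frozenset(b))
        out.append(frozenset(i + n for i in b))
    for factor in _one_factorization(n):
        for (a, b) in factor:
            for (c, d) in factor:
                out.append(frozenset({a, b, c + n, d + n}))
    return out


def construct_codebook(n_bits: int) -> Codebook:
    """Maximal weight-4, distance-4 codebook by Steiner-quadruple doubling.

    Supported for n_bits a power of two >= 4.  Every 3-subset of bit
    positions is covered by exactly one barcode; the resulting code size
    is C(n_bits, 3)/4.  Entries are emitted as unassigned blanks in
    lexicographic bit-position order; :func:`assign_barcodes` names them.
    """
    if n_bits < 4 or n_bits & (n_bits - 1):
        raise ValueError("n_bits must be a power of two >= 4")
    blocks = [frozenset({0, 1, 2, 3})]
    n = 4
    while n < n_bits:
        blocks = _double_sqs(blocks, n)
        n *= 2
    blocks.sort(key=sorted)
    entries = []
    for k, b in enumerate(blocks):
        code = [0] * n_bits
        for i in b:
            code[i] = 1
        entries.append(
            CodebookEntry(name=f"Blank-{k + 1}", barcode=tuple(code), is_blank=True)
        )
    return Codebook(entries=entries, n_bits=n_bits)


def assign_barcodes(genes: list[str], cb: Codebook, seed: int) -> Codebook:
    """Assign each gene a distinct barcode (seeded random draw); remaining
    entries become Blank-1, Blank-2, ..."""
    if len(genes) > len(cb):
        raise ValueError(
            f"codebook capacity {len(cb)} cannot host {len(genes)} genes"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cb))
    entries: list[CodebookEntry | None] = [None] * len(cb)
    for g, idx in zip(genes, order):
        entries[idx] = CodebookEntry(
            name=g, barcode=cb.entries[idx].barcode, is_blank=False
        )
    k = 0
    for idx in range(len(cb)):
        if entries[idx] is None:
            k += 1
            entries[idx] = CodebookEntry(
                name=f"Blank-{k}", barcode=cb.entries[idx].barcode, is_blank=True
            )
    return Codebook(entries=entries, n_bits=cb.n_bits)


# ---------------------------------------------------------------------------
# encoding-probe target regions


@dataclass(frozen=True)
class ProbeParams:
    window_len: int = 30
    gc_range: tuple = (0.40, 0.60)
    gc_range_relaxed: tuple = (0.30, 0.70)
    tm_range: tuple = (66.0, 76.0)
    tm_range_relaxed: tuple = (61.0, 81.0)
    max_homology: int = 15
    n_target: int = 64
    min_probes: int = 40
    max_overlap_relaxed: int = 20

    def __post_init__(self) -> None:
        if self.window_len <= self.max_homology:
            raise ValueError("window_len must exceed max_homology")
        for lo, hi in (self.gc_range, self.gc_range_relaxed, self.tm_range, self.tm_range_relaxed):
            if lo >= hi:
                raise ValueError("range bounds must be ordered")


@dataclass
class TargetRegionResult:
    windows: list[tuple]  # (start, end) half-open, 0-based
    rule_set: str  # "primary" | "relaxed"
    rejected: bool


def build_kmer_index(sequences, k: int = 16) -> set:
    """Exact k-mer index of the exclusion sequences (rRNA/tRNA).

    A window is homologous if it shares any (max_homology+1)-mer with the
    exclusion set; screening "no homology longer than 15 nt" therefore
    uses k = 16.
    """
    index: set = set()
    for seq in sequences:
        s = str(seq).upper()
        index.update(s[i : i + k] for i in range(len(s) - k + 1))
    return index


def _default_tm(window: str) -> float:
    from Bio.SeqUtils import MeltingTemp

    return float(MeltingTemp.Tm_NN(window))


def design_target_regions(
    transcript: str,
    excluded_index: set,
    params: ProbeParams = ProbeParams(),
    seed: int = 0,
    tm_func=None,
) -> TargetRegionResult:
    """Select 30-nt probe target windows on a transcript.

    All windows passing the GC, melting-temperature and homology filters
    are enumerated; a seeded random subset of ``n_target`` mutually
    non-overlapping windows is drawn.  If the transcript cannot host that
    many, the relaxed rule set applies (wider GC/Tm ranges, overlap up to
    ``max_overlap_relaxed`` nt, at least ``min_probes`` windows); genes
    still below ``min_probes`` are flagged rejected.

    ``tm_func`` maps a window string to a melting temperature in Celsius;
    the default is Biopython's nearest-neighbor model.  It is injectable
    because Tm filters depend on the thermodynamic parameter set and salt
    correction in use.
    """
    tm_func = tm_func or _default_tm
    seq = transcript.upper()
    L = len(seq)
    w = params.window_len
    if L < w:
        return TargetRegionResult(windows=[], rule_set="primary", rejected=True)
    k = params.max_homology + 1

    def candidates(gc_range, tm_range):
        out = []
        for start in range(L - w + 1):
            win = seq[start : start + w]
            gc = (win.count("G") + win.count("C")) / w
            if not gc_range[0] <= gc <= gc_range[1]:
                continue
            if excluded_index and any(
                win[i : i + k] in excluded_index for i in range(w - k + 1)
            ):
                continue
            if not tm_range[0] <= tm_func(win) <= tm_range[1]:
                continue
            out.append((start, start + w))
        return out

    def pick(cands, max_overlap, rng):
        order = list(cands)
        rng.shuffle(order)
        chosen: list[tuple] = []
        min_gap = w - max_overlap
        for win in order:
            if all(abs(win[0] - c[0]) >= min_gap for c in chosen):
                chosen.append(win)
                if len(chosen) == params.n_target:
                    break
        return sorted(chosen)

    rng = np.random.default_rng(seed)
    primary = pick(candidates(params.gc_range, params.tm_range), 0, rng)
    if len(primary) >= params.n_target:
        return TargetRegionResult(windows=primary, rule_set="primary", rejected=False)
    rng = np.random.default_rng(seed)
    relaxed = pick(
        candidates(params.gc_range_relaxed, params.tm_range_relaxed),
        params.max_overlap_relaxed,
        rng,
    )
    if len(relaxed) >= params.min_probes:
        return TargetRegionResult(windows=relaxed, rule_set="relaxed", rejected=False)
    best = relaxed if len(relaxed) >= len(primary) else primary
    rule = "relaxed" if best is relaxed else "primary"
    return TargetRegionResult(windows=best, rule_set=rule, rejected=True)
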