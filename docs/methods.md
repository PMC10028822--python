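# Methods

This note documents the models and procedures implemented in
`brainatlas`, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Barcode codebooks

MERFISH-style barcodes are binary words of fixed length n read out over
n imaging bits. Error robustness requires constant Hamming weight 4
(four "on" bits per gene, so single losses and gains are detectable)
and minimum pairwise Hamming distance 4 (single-bit errors are
correctable). Two weight-4 words are at distance ≥ 4 exactly when they
share at most two on-bits, i.e. no 3-subset of bit positions lies in two
words. A maximal codebook is therefore a Steiner quadruple system
SQS(n): a family of 4-subsets covering every 3-subset exactly once, of
size C(n,3)/4, which exists for n ≡ 2 or 4 (mod 6).

`construct_codebook` builds SQS(n) for n a power of two by the classical
doubling recursion. Given SQS(n) on points X and a one-factorization
F₁…F_{n−1} of the complete graph on X (round-robin circle method),
SQS(2n) on X×{0,1} consists of (i) each block replicated in each point
copy and (ii) the cross blocks {a₀, b₀, c₁, d₁} for every ordered pair
of (possibly equal) edges {a,b}, {c,d} of the same one-factor. Triples
within one copy are covered by (i); triples spanning copies are covered
exactly once by (ii) because an edge lies in exactly one factor and each
point lies in exactly one edge of a factor. Sizes: 1, 14, 140, 1240 for
n = 4, 8, 16, 32. `validate_codebook` checks weights and all pairwise
distances exhaustively (vectorized O(n²)); `max_code_size` returns
C(n,3)/4 for the exact cases and the generalized packing bound
⌊C(n,w−1)/w⌋ (flagged non-exact) otherwise, with an optional
branch-and-bound search for n ≤ 10 that proves the maximum by combining
lexicographic search with the triple-packing bound.

## Panel design

Differential expression between cluster pairs uses a two-sided Wilcoxon
rank-sum test on total-normalized counts. The test choice is a design
decision — the selection is dominated by the effect-size gates anyway:
fold change ≥ 2 of normalized means, p < 0.01, foreground expressing
fraction ("expressed" = count > 0) ≥ 0.5, and expressing-fraction ratio
> 3.3. Each direction is ranked by p and truncated to 50. Panel assembly
is greedy: starting from a curated list, the cluster-pair direction with
the worst coverage receives its best-ranked missing gene until every
direction has ≥ 3 panel genes or its pool is exhausted (exhausted pairs
are reported, not raised). Pool trimming removes genes with fewer than
40 candidate probes or a maximal per-cluster mean above 3000 counts
(both strict, following the stated wording).

Probe target regions are 30-nt windows filtered by GC fraction
(0.40–0.60), melting temperature (66–76 °C), and homology: a window is
excluded if it shares any 16-mer with the rRNA/tRNA exclusion set (the
exact-k-mer reading of "no homology longer than 15 nt"). A seeded random
non-overlapping subset of 64 windows is drawn; transcripts that cannot
host 64 fall back to relaxed rules (GC 0.30–0.70, Tm 61–81 °C, overlap
up to 20 nt, minimum 40 windows). The Tm model is injectable (default:
Biopython nearest-neighbor) because the filter outcome depends on the
thermodynamic parameter set and salt correction in use; tests exercise
the filter logic with a stubbed Tm.

## Preprocessing

Order: volume filter → volume normalization → mean rescale → quantile
filter → doublet hook. Volume windows per z-plane count: 3 planes
50–1500 µm³, 5 planes 80–2500 µm³, 6 planes 100–3000 µm³; all
comparisons strict, so boundary values survive. Counts are divided by
the imaged volume and rescaled so the mean per-cell total is 250.
Cells in the top and bottom 1% total-count quantiles are removed
(numpy's linear-interpolation quantile convention; applied per input
table). Neurotransmitter groups are assigned from raw integer counts —
the threshold (any marker ≥ 2 counts) is a copy-number statement —
with overlapping groups allowed (e.g. Glut+Gaba co-expression). Doublet
scoring itself is external; the hook removes cells with a provided
score strictly above 0.25.

## Integration

Both datasets are standardized per round: totals to 1000, log1p,
per-gene z-scores (numerically constant genes become zero columns).

Integration partitions group subclasses that are close in transcription
space: a kNN graph (k = 15) of reference cells in 100-dimensional PCA
space is collapsed to a subclass graph whose edge weights count
cross-subclass kNN edges, then split into balanced parts (by cell
count, tolerance 34%) minimizing cut weight with a seeded greedy
initialization plus single-node refinement, best of 8 restarts. The
objective (balanced parts, minimal cut), not any particular partitioner
implementation, is the contract; an external k-way partitioner can be
substituted. The default part count scales as ⌈#subclasses/6.4⌉.

Co-embedding uses diagonal CCA: with unpaired cells the shared axis is
genes, so the canonical vectors are the singular vectors of the
cell-by-cell cross-product X Yᵀ of the standardized (and, above 100 000
cells, seeded-downsampled) matrices, computed economically through QR
factorizations. The corresponding gene-space maps project the full
datasets, and per-cell embeddings are L2-normalized. Anchors are all
cross-dataset mutual 5-nearest-neighbor pairs, ties broken by index.

Label transfer votes among each measured cell's 100 nearest anchor
reference-cells in the joint PCA space of the combined standardized
data (ties broken lexicographically); the confidence score is the
winning label's fraction. Round 1 transfers partition labels on the
panel genes; round 2 runs per partition on the partition's positive-
log-dispersion genes (variance/mean > 1 on counts normalized to the
median total — a scale-free criterion) and transfers subclass and
cluster labels. Because a label is only right when both rounds were
right, final confidences are the round-2 confidence times the partition
confidence; pass gates are > 0.8 (subclass) and > 0.5 (cluster).
Whether round-2 neighbor searches should use partition-local PCA or CCA
coordinates is not determined by the source procedure; partition-local
joint PCA is used (configurable).

Imputation averages the reference log-normalized expression of the 30
nearest anchor reference-cells with Gaussian-kernel weights
w = exp(−(d/σ)²), adaptive bandwidth σ equal to the distance to the
30th anchor, normalized to sum to one — so imputed values are convex
combinations of reference profiles. The kernel form is a design
decision (only "weights based on the distance" is specified) and is
configurable. The cosine-mapping cross-check assigns each cell to the
cluster profile at minimum cosine distance and is used to measure
method agreement, never as the primary assignment.

## Region statistics

Fraction-mode enrichment of type t in region r is
(n_tr/n_·r)/(n_t·/n_··); density mode divides by region volumes
instead. Fraction mode is the default because it needs no volume map;
density phrasing applies to anatomical regions, fraction phrasing to
spatial modules. Local complexity is the number of distinct subclasses
among a neuron's 50 nearest neighbor neurons, per section, Euclidean,
ties by index; sections with too few neurons are flagged rather than
scored. Region splitting cuts at the midpoint of the ccfx range; cells
exactly at the cut go posterior.

## Spatial modules

Each cell i receives weights over its 50 spatially nearest eligible
neighbors, w_ij = exp(−(D_ij/D0_i)²), with D0_i equal to twice the
distance to the 5th nearest neighbor at level 1 and to that distance
itself at level 2 (finer spatial resolution). Summing weights per cell
type and L2-normalizing yields the composition vector; at level 2 the
subclass-based vector is concatenated with the cluster-based vector
before normalization. Neighborhoods never cross sections; level 1
excludes vascular/immune cells, level 2 uses neurons only (the caller
supplies eligibility).

Clustering is Leiden (RB-configuration, resolution 1.0, seeded) on the
unweighted kNN graph (k = 15) of the vectors; exactly duplicated
vectors are collapsed to one node first so ties among identical points
cannot split arbitrarily. Raw Leiden at this resolution intentionally
over-fragments region-scale structure; the full `delineate_modules`
pipeline therefore merges modules whose centroid cosine similarity
exceeds 0.9 iteratively — the programmatic counterpart of the manual
curation step that merges clusters lacking clear spatial boundaries.
Recovery of the two-region fixture is insensitive to this threshold
over 0.7–0.9. Level-2 modules are computed per level-1 module and
labelled `<level1>.<local>`, so nesting holds by construction.

## Gradients

Neighbourhood purity is the fraction of same-cluster cells among the 50
nearest neighbors in expression space (top-50 PCA of the standardized
log-normalized matrix; invariant to global rescaling). Cluster
discreteness is mean purity; a subclass is summarized by the median
over its clusters. The gradient axis is PC1 of the standardized
expression by default; a pseudotime variant projects cells onto a
polyline through running means along PC1 (a light-weight principal
curve adequate for monotone gradients). Signs are flipped so the
correlation with the supplied spatial coordinate is non-negative.
Callers that pass already-normalized expression can disable the
internal log-normalization. Spatial correlations are Pearson r with a
Fisher-z 95% interval; the spatial coordinate (cortical depth, atlas
axes) is supplied by the caller.

## Cell-cell interactions

Proximal pairs are unordered cross-type (or within-type, counted once)
pairs at centroid distance strictly below R_proximal — 15 µm (soma
scale) in strict mode, 30 µm in relaxed mode. Counting uses a k-d tree
with the radius tightened to the largest float below R so the ≤ of the
tree query realizes the strict <; tests pin the tree count to the O(n²)
oracle. Pairs never span sections.

The null displaces every cell independently and uniformly within a
100 µm disk, in plane, per round (default 1000 rounds; the calibration
and power suites use 200), recounting proximal pairs each round; all
types are displaced together so one set of rounds serves every pair of
a region. Displaced positions are reflected at the section's bounding
box: without reflection, edge cells leak out of the imaged window, the
null mean is biased low, and the type-I error on a 1×1 mm section at
complete spatial randomness is badly inflated. The per-pair null is
summarized as a fitted normal (sd floored at 10⁻⁹); the p-value is the
larger of the fitted-normal upper tail and the empirical randomization
tail, floored at 1/(rounds+1) — the normal fit alone has slightly light
tails on discrete counts. BH correction runs across the pairs of a
region; a call requires adjusted p < 0.05 and ≥ 20 observed pairs.
Self pairs are computed and flagged. Relaxed-mode (30 µm) calls
additionally require at least one significant ligand-receptor pair.

The ligand-receptor score for cells (i,j) and pair k is
S = ln(1 + ∏_p L_p(i) · ∏_q R_q(j)) over the subunits; the literal
all-cross-terms product (∏L)^|q|·(∏R)^|p| is available behind a flag.
Imputed expression is preferred, measured expression is the fallback,
and pairs with missing subunit genes are skipped with a warning. Scores
over all proximal pairs are compared with an equal-size seeded sample
(without replacement) of non-proximal pairs by a one-sided Welch
t-test, BH-corrected per type pair; significance requires mean fold
≥ 2, adjusted p < 0.01, and a positive score in ≥ 40% of proximal
pairs. Pairs sharing a cell are not deduplicated (their scores are not
independent; the procedure inherits this simplification knowingly).
Proximity-dependent upregulation splits type-A cells by whether any
type-B cell lies within R_proximal and applies the same Welch/BH
machinery per highly variable gene (fold ≥ 2, adjusted p < 0.01).

Type eligibility per region: cells gated at subclass confidence > 0.8;
neuronal subclasses need enrichment ≥ 6 in the designated
high-complexity regions (the subdivided hypothalamic/midbrain/hindbrain
regions) and ≥ 2 elsewhere; astrocytes ≥ 1; other non-neuronal types
need more than 50 cells in the region.

## Synthetic data

The generator emulates the statistical structure the analyses assume:
homogeneous Poisson parent points per region at stated per-subclass
intensities (cells/mm²); negative-binomial counts around per-cluster
mean profiles, variance m + m²/r (r = ∞ gives Poisson); per-cell
volumes lognormal around 300 µm³ (σ = 0.25) with counts scaling
proportionally before QC, so volume normalization is exercised
nontrivially; linear mean shifts along a spatial axis for gradient
genes; Thomas-like attraction (each type-A parent spawns a type-B
daughter uniformly within a radius with a given probability); and
ligand/receptor mean multipliers applied to cells within a stated
radius of a partner of the other type. Sections are 2D (distance
thresholds are of section scale; z within a 10-µm section is ignored)
and multi-section experiments are lists of independent sections.

Named fixtures define the study conditions for the validation suites:

- `csr` — two types at 200 cells/mm² each on 1×1 mm, no interaction
  (type-I error calibration).
- `attraction` — the same with attach probability 0.5 at radius 10 µm
  (power).
- `two_region` — two 1×1 mm rectangles with disjoint dominant
  subclasses at 1200 cells/mm² plus a shared 100 cells/mm² background
  (module recovery). Region extent is large relative to the
  50-neighbor radius so boundary-blended composition vectors stay a
  small minority.
- `gradient` — one subclass with 16 genes rising linearly 1→11 counts
  across 1 mm (dispersion 20) beside a subclass with three
  well-separated clusters (gradient recovery and the discreteness
  contrast).
- `lr_effect` — a sparse 2.5×2.5 mm section (25 cells/mm² per type,
  attach probability 0.25) with a 3-fold ligand/receptor upregulation
  within 30 µm on one database pair. Sparsity matters: at higher
  densities most cells are within 30 µm of some partner, the "non-
  proximal" control pairs inherit the planted effect, and the fold
  criterion becomes unmeasurable regardless of the planted effect size.
- `integration` — 10 subclasses × 3 clusters over 150 genes with
  block-marker profiles, 100-gene measurement panel; the withheld 50
  genes exercise imputation.

What the generator does **not** emulate: optics and spot decoding,
barcode misidentification, segmentation errors, doublets, 3D structure,
curved region boundaries, batch effects between animals, and the
(306-subclass, 5200-cluster) scale of a real atlas. Passing suites
therefore demonstrate correctness and calibration of the procedures
under their stated assumptions, not end-to-end performance on real
tissue.

## Problem sizes

The validation suites run at deliberately modest sizes: 20 seeds × 200
randomization rounds for calibration/power, reference draws of 100
cells per cluster (3000 cells) with 1500 measured cells for transfer
and imputation, ~5000 cells per two-region section over 5 seeds for
module recovery. These sizes give the planted effects comfortable
margins while keeping the whole suite under a minute of compute for the
statistical parts; all thresholds are the ones stated above, not
adjusted per size.

## Known limitations

- The balanced partitioner is greedy with restarts; on adversarial
  graphs it may miss the optimal cut (tests pin it to the brute-force
  optimum only on small instances).
- The pseudotime variant is a polyline projection, not a full
  principal-curve fit; for strongly curved manifolds PC1 seeding can
  mis-order cells.
- Welch tests over cell pairs ignore the dependence between pairs
  sharing a cell.
- The normal-fit null assumes unimodal randomization counts; extremely
  sparse regions are protected only by the empirical-tail floor and the
  20-pair observation gate.
- `max_code_size` is exact only for weight 4, distance 4, n ≡ 2, 4
  (mod 6); other parameters get an upper bound.
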