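# Methods

This note documents the models, estimators, numerical choices and
limitations of `pdmg`, in the order the pipeline runs them.

## Normalization and filtering (`pdmg.preprocess`)

**Low-expression filter.** A gene is kept iff its CPM reaches `min_cpm`
(default 1) in at least `ceil(min_prop × smallest group size)` columns
(default `min_prop` 0.7).  The rule is idempotent and order-preserving.  For
cell-level matrices, where most genes are sparse, the pipeline lowers
`min_prop` to 0.1.

**TMM.** Between-sample factors are the trimmed mean of M-values: against a
reference column (the one whose upper-quartile count rate is closest to the
mean upper-quartile), gene-wise M = log2 ratio and A = mean log2 abundance
are computed on genes positive in both columns, doubly trimmed (30% per M
tail, 5% per A tail, A > −1e10), and averaged with inverse
asymptotic-variance weights `(N−y)/(Ny)` summed over the pair; factors are
rescaled to geometric mean 1.  The implementation agrees with the
Bioconductor reference to 1e-9 on random matrices (frozen oracle values in
the tests).  One numerical consequence worth knowing: the variance weights
contain 1/N library-size terms, so the factors are *exactly* invariant to a
common rescaling of all columns but only O(1/N)-invariant (≈1e-3) to
rescaling a single column; M, A and the trim sets themselves are exactly
scale-free.

**log-CPM.** `log2((count + c) / ((lib × factor + 2c) / 1e6))` with a fixed
prior count c = 0.5.  The originating workflow selects the log prior by an
optimization that is not reproducible from its description; a fixed prior
was chosen because all downstream stages depend only on monotone log-CPM.

**Dominant-gene filter.** Any gene whose share of a dataset's transcripts
exceeds `max_fraction` (default 0.40) is removed and reported.  The default
sits just below the lowest dominance observed for GFAP in the motivating
tissue data (49–89% of transcripts), so such a gene is always caught while
ordinary panel genes (≈1% each) never are.  At most `floor(1/max_fraction)`
genes can be removed.

## Statistical kernels (`pdmg.stats`)

**Wilcoxon rank-sum.** U counts pairs with x > y plus half the ties
(mid-ranks).  The exact path enumerates all C(n, n_x) group assignments of
the pooled values — valid under ties — and reports 2·min(tails) clipped at
1; `auto` uses it for n ≤ 14 without ties, otherwise a normal approximation
with tie-corrected variance and 0.5 continuity correction.  The exact path
is tested against an independent full-enumeration oracle on 500 random tied
instances.

**NB likelihood-ratio test.** Counts are modeled NB(μ, φ) with variance
μ + φμ², log link and fixed log-library offsets.  Group-specific and common
means are fitted by Newton–Raphson on the score Σ(y−μ)/(1+φμ) (all-zero
responses give μ = 0 with log-likelihood 0), and 2·Δℓ is referred to χ²(1).
As φ → 0 the statistic converges to the Poisson LRT; on null simulations
(μ = 50, φ = 0.1, 5 vs 5) the empirical size at α = 0.05 is ≈ 0.05 and the
p-values are near-uniform.

**Dispersion.** When not supplied, φ is the pooled method of moments: per
gene and group, (var − mean)/mean² on depth-adjusted counts, pooled by the
*mean* across genes.  The per-gene estimate is unbiased but right-skewed at
small n, so a median would pool ≈15% low and make the test liberal.

**BH FDR.** Step-up `q_(i) = min_{j≥i} p_(j)·m/j` clipped at 1.  Note that
the map p → q is *not* idempotent (p = [0.1, 0.9] → q = [0.2, 0.9] →
[0.4, 0.9]); constant vectors are its fixed points.  Correctness is tested
against the statsmodels implementation and a hand-worked example.

**Enrichment and correlation.** Over-representation uses the upper-tail
hypergeometric P[X ≥ k] (checked against brute-force pmf summation);
sample-similarity uses Spearman correlation with mid-ranks, undefined (an
error) on constant vectors.

**ssGSEA.** For one profile, genes are ranked by descending expression (ties
broken by gene id), and the score accumulates the difference between the
rank-weighted (weight = rank value^0.25) cumulative fraction of set members
and the unweighted cumulative fraction of non-members.  The unweighted
(α = 0) variant is zero-mean for random sets; the weighted default carries
the statistic's well-known positive null offset, so scores should be
compared between sets or samples, not to zero.

## Consensus signature (`pdmg.signature`)

Per modality, the DEG list (q < α, default α = 0.05) is tested for
over-representation in each gene set (hypergeometric + BH across sets).
Sets significant in both modalities that contain at least one significant
gene from each modality survive; the signature is the union of their
significant genes.  A gene significant in both modalities is kept only when
the signs agree — conflicting genes are excluded and logged rather than
majority-voted, because "follows the signature" is undefined for a gene the
two modalities move in opposite directions.  The construction is invariant
to set order and naming, and tightening α never adds genes.  Proprietary
pathway-analysis internals are deliberately replaced by this transparent
set-membership logic: the cross-modality filter is membership-based and does
not depend on the enrichment engine.

## Deconvolution (`pdmg.deconvolution`)

The reference summarizes a multi-donor single-nucleus matrix into per-type
relative profiles (per donor and pooled), cross-donor per-gene variances and
mean per-cell library sizes.  A bulk column b (normalized to relative scale)
is fitted by non-negative least squares `min ‖W^{1/2}(b − Mp)‖` where M's
columns are pooled profiles × mean library size and `W = diag(1/(v + ε))`
with ε = 1e-8 flooring zero variances; p is normalized to proportions.  This
keeps the core idea of multi-subject deconvolution — down-weighting genes
whose type profiles are donor-unstable — in a single deterministic pass
instead of the recursive re-weighted scheme.  Proportions are invariant to
bulk scaling; exact mixtures are recovered to 1e-6; NB-noised Dirichlet
mixtures are recovered with RMSE ≈ 0.02.  Class-level summaries average
member proportions per cell type without renormalization (the radar-chart
convention, under which reported sums need not be 100).

## Spatial analysis (`pdmg.spatial`)

**Assignment.** Coordinates are 0-based pixels (x right, y down); a
transcript at (x, y) falls in mask pixel (⌊y⌋, ⌊x⌋).  It is assigned to that
pixel's label, or — within a Euclidean expansion radius (default 8 px,
matching the segmentation's cell-expansion setting) — to the nearest labeled
pixel, ties to the lowest label (implemented with a KD-tree over labeled
pixels; k = 16 nearest candidates bound the tie search).  Everything else is
unassigned.  Every mask label becomes a cell, including zero-count cells: no
cell is filtered by transcript count.  Conservation (assigned + unassigned =
table rows) and equality with a brute-force nearest-pixel oracle are tested.

**Clustering and annotation.** Cells are depth-normalized as
log2(1 + 10⁴·count/total); the 10 highest-variance genes feed a 5-component
PCA and k-means over k = 2..8, k chosen by maximal mean silhouette,
deterministic given the seed.  Clusters are annotated by the marker set with
the highest mean z-scored expression; a winning margin < 0.1 yields
"unknown".  With only 10 variable genes the rarest cell type (endothelial,
10% of cells, 3 markers) is not always resolved as its own cluster;
microglia — the population the pipeline is about — separate cleanly
(recall ≥ 0.9 end-to-end, 1.0 in the seeded tests).

## Classification and reporting (`pdmg.classify_report`)

For each disease-donor microglial cell, per panel-resident signature gene g
the deviation `d_g` from the healthy reference (mean log-normalized
expression of control-donor microglia; median available) *agrees* iff
`sign(d_g) = direction(g)` and `|d_g| > ε`.  The cell is consensus iff the
agreement fraction ≥ τ.  Defaults τ = 1 (every gene must follow the
signature — the strict reading of "deregulated in the same manner",
consistent with the small 5.4% consensus class) and ε = 0 (no magnitude
threshold is stated anywhere); both are config knobs.  With τ = 0 any cell
with ≥ 1 agreement is consensus; with τ slightly above 1, none is.
Classification is invariant to per-cell depth because the log-normalization
absorbs totals.  Control cells are labeled healthy and never classified.

Class summaries per gene: distribution percentages
`100·mean_k / Σ_j mean_j` on expm1 of log-normalized values (NaN-flagged
when all class means are 0), pairwise Wilcoxon q-values, and presence
categories — "expressed" in a class means detected in ≥ max(2,
⌈0.01·class size⌉) cells; the presence pattern plus the DE calls yields
all-classes / consensus-enriched / non-consensus-depleted / class-specific /
class-absent / none.

## Synthetic data (`pdmg.synthetic_data`)

The generator's defaults are the study conditions; what they emulate and
what they do not:

* **Gene universe**: 2000 generic genes plus named marker genes (4 microglia,
  3 each for astrocyte / neuron / oligodendrocyte / endothelial) and a
  dominant GFAP-like gene.  Baseline abundances are log-normal (meanlog 1,
  sdlog 1) — a realistic dynamic range; no distribution is prescribed by the
  source material.
* **Signature**: genes drawn without replacement from the generic pool,
  directions Bernoulli(0.5), bulk/sn effect 2^±1.  40 genes for the
  two-modality recovery studies; the default end-to-end pipeline plants 10
  genes (concentrated in 2 of 50 gene sets) so that the signature fits
  meaningfully on a 100-gene spatial panel.
* **Bulk**: NB counts (Poisson–Gamma, var = μ + φμ², φ = 0.1) at
  Poisson-varying depth 1e6, 6 samples per group.
* **Single-nucleus**: 5 donors per group (the source midbrain cohort had
  6 PD / 5 control), 150 cells per donor, ~4000 counts per cell (typical
  nucleus depths), cell types multinomial with microglia 0.3 / astrocyte,
  neuron, oligodendrocyte 0.2 / endothelial 0.1 — placeholders, since the
  cellular composition of PD midbrain is not quantified in the source.
  Type profiles share the baseline modulated per (gene, type) (log-normal
  sd 0.5) with markers ×8 in their own type.  A per-donor log-normal random
  effect of sd 0.1 perturbs gene means: large enough that cross-donor
  variances differ and deconvolution weighting matters, small enough that
  cell-level rank tests are not dominated by between-donor pseudoreplication
  (at sd 0.3, 5 donors/group and hundreds of cells, most genes become
  "significant" and set enrichment collapses — a real hazard of cell-level
  DE that the note flags rather than hides).
* **Spatial**: non-overlapping disc cells of radius 8 px placed by
  rejection sampling (bounded retries, then an error); transcript positions
  uniform in the disc; counts NB from type profiles with signature genes at
  mean 10 in microglia.  Condition (50% PD) and type counts are apportioned
  deterministically (largest remainder), so 4354 cells yield exactly 653 PD
  microglia.  A planted fraction (default 0.054) of PD microglia gets all
  signature-gene means shifted by 2^±2.5 — stronger than the bulk effect
  because a strict all-gene concordance call on ~10 counts/gene needs
  per-gene agreement ≈ 0.99 for the class to be recoverable; with these
  values recovery is 85–100% of planted cells with ≲1 false positive.  The
  dominant gene is emitted half inside cells, half as uniform background,
  totaling its configured share (default 0.6, inside the observed 49–89%
  range) of all transcripts.
* **Not emulated**: tissue morphology, irregular cell shapes, optical noise,
  z-stacks, doublets, segmentation errors, batch effects, ambient RNA.
  Passing recovery tests therefore demonstrates the correctness of the
  computational chain under its stated model, not robustness to the failure
  modes of real tissue data.

## Problem sizes

The test suite (~30 s) and the acceptance script (~5 s) use: 2000-gene
universes for signature recovery and LRT calibration; 4354 spatial cells
(653 PD microglia) on a 1600² field for classification; 20 mixtures for
deconvolution; 300-gene comparisons for the DE-operation recovery checks,
where 40 true effects leave the BH threshold enough headroom for the
recall/precision targets (at 40-in-2000 the same thresholds are
statistically unreachable for any calibrated test at n = 6 per group).

## Known limitations

* The NB LRT uses a single pooled dispersion, no per-gene shrinkage or
  moderation; with few replicates and gene-specific dispersions it can be
  mis-calibrated per gene.
* Cell-level Wilcoxon DE treats cells as independent; donor effects inflate
  its discovery list (pseudoreplication).  Pseudobulk aggregation is out of
  scope by design.
* The deconvolution is single-pass; it inherits MuSiC's weighting idea but
  not its recursive tree-guided refinement.
* τ = 1 makes the consensus call sensitive to any panel gene with weak
  expression; users with noisier panels should lower τ or raise ε.
* k-means + silhouette can merge rare cell types when the 10-gene variable
  selection carries no markers for them.
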