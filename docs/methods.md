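# Methods

This note documents the models, defaults, and numerical choices behind
`duplipath`, and what the synthetic-data generator does and does not
emulate.

## Gene catalog and census

Gene identifiers follow the upland-cotton reference grammar
`Gohir.<A|D><chromosome 01–13>G<6-digit locus>[extra digits]`; the optional
trailing digits accommodate split gene models (e.g. `Gohir.A09G192401`).
Parsing and formatting are exact inverses on valid identifiers.

Homoeolog pairing uses, in order of precedence: (1) an explicit partner
column in the catalog; (2) reciprocal best global-alignment identity among
unannotated genes restricted to the same family and chromosome number, with
ties broken deterministically by the lowest locus number. Protein alignment
is global (Needleman–Wunsch via Biopython's `PairwiseAligner`) with
BLOSUM62, gap open 10, gap extend 0.5 — configurable, since published
identity percentages depend on the scoring scheme and on whether the
denominator is the alignment length (used here, gaps included) or the
shorter sequence.

## Differential expression

Counts are normalized by median-of-ratios size factors (reference = per-gene
geometric mean; genes with any zero excluded from the reference). The
per-gene model is negative binomial with var = μ + αμ².

Dispersion: a method-of-moments estimate pooled over the two condition
groups, with the unbiased denominator m² − s²/n (the naive m² denominator
underestimates α noticeably at n = 3). Per-gene estimates are shrunk toward
a parametric trend α(μ) = a₀ + a₁/μ fit by least squares **on the natural
scale**. Two choices here matter and were made deliberately after measuring
null calibration at the study's 3 vs 3 design:

- fitting or averaging log-dispersions is badly biased downward when the
  per-gene estimates are as noisy as they are at three replicates (the heavy
  left tail dominates), which in turn inflates the type-I error at high
  dispersion — hence the natural-scale trend;
- the per-gene estimate carries so little information at n = 3 that the
  final dispersion is trend-dominated: final = 0.1·own + 0.9·trend
  (`shrink_weight = 0.1`). Genes whose sample variance fell below the mean
  contribute nothing and take the trend value outright.

The Wald statistic log₂FC / SE (delta-method SE of the log ratio, with a
pseudocount of 0.5 stabilizing near-zero means) is referred to the standard
normal. With the trend-dominated dispersion this combination keeps the
empirical null rejection rate at nominal 0.05 within ±0.015 across
dispersions 0.01–0.5 (measured on 2000-gene null simulations over multiple
seeds). DEG thresholds are padj < 0.05 (Benjamini–Hochberg step-up,
implemented directly and cross-checked against statsmodels in the tests)
and |log₂FC| > 1, on the unshrunken fold change.

FPKM is count·10⁹/(total·length); totals default to per-library column sums
but mapped-fragment totals can be passed instead.

## Homoeolog bias classification

Within each condition, At vs Dt equality is tested by Welch's t on
log2(x+1)-transformed replicate values at α = 0.05 per ratio, uncorrected
across pairs — the classification rule treats each ratio's 0.05 threshold
as part of its definition. A nonsignificant ratio is recorded as 1. Pairs
are classified only when both homoeologs average ≥ 1 FPKM in both
conditions ("simultaneously expressed"; configurable). Zero-variance
degenerate inputs are called significant iff the means differ, so noiseless
synthetic data classify cleanly.

The (CK, UV) verdict pair maps onto six categories (no/lost/At/Dt/get-At/
get-Dt bias). A dominance switch (At-dominant CK, Dt-dominant UV or vice
versa) has no name in the six-way taxonomy; it is labeled by the
UV-dominant homoeolog and flagged `switched_dominance`.

A structural consequence of the per-ratio α: planted-truth recovery does
not converge to 100% with more replicates. Categories requiring an "equal"
verdict are capped at 1−α per ratio (no bias at ≈0.95² ≈ 0.90), so overall
recovery approaches ≈0.96 on an even six-category mixture. The tests assert
the attainable ceiling, and 100% only for the doubly-significant
categories.

## Weighted co-expression and regulator screening

Unsigned adjacency a_ij = |Pearson r|^β on log-transformed expression
across the multi-stress panel; constant genes are dropped with a warning.
β is the smallest power in 1–20 whose scale-free fit R² exceeds 0.85,
falling back (with a warning) to the best-fitting power. The fit regresses
log₁₀ density of connectivity on log₁₀ connectivity over quantile bins
(equal gene counts, density = count/(n·width)); equal-width binning leaves
the sparse hub tail to dominate and is noticeably less stable.

TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with l_ij = Σ_u a_iu a_uj,
computed vectorized and verified entrywise (<1e-12) against a triple-loop
oracle. Modules: average-linkage clustering of 1 − TOM, static cut at
height 0.99, minimum size 30, iterative merging of modules whose eigengenes
(sign-anchored first principal components) correlate above 0.75. This is a
deliberate simplification of dynamic hybrid tree cutting; defaults are
configurable and recorded in the run manifest.

Regulator→target edges are pairs (candidate TF, structural gene) with TOM
weight ≥ 0.2; the weight cutoff applies to the TOM because that is the
weighted-edge matrix the network export emits. The regulation sign
(activation vs repression; solid vs dashed edge in viewers) comes from the
sign of the underlying Pearson correlation. Export is Cytoscape SIF plus a
TSV attribute table that round-trips weights at 6 decimals.

## qPCR (2^−ΔΔCt)

ΔCt = Ct_target − Ct_reference per replicate; ΔΔCt subtracts the **mean**
control ΔCt, so control-condition folds keep their replicate spread (their
geometric mean is 1 by construction) and the reference gene against itself
gives fold ≡ 1 exactly. Conditions are compared by Welch's t on ΔCt;
significance stars: * p < 0.05, ** p < 0.01.

## Synthetic data: what it emulates, and what it does not

Defaults mirror the study design: 125 loci (80 dual / 18 At-only / 27
Dt-only → 205 genes), 12 structural enzyme families with GST dominant,
3 CK + 3 UV replicates, NB dispersion 0.05 around a baseline mean of 500
counts, per-sample library-size factors log-uniform in [0.7, 1.4], planted
DEGs at |log₂FC| = 2, bias dominance shifts of 4-fold (unambiguous at
n = 3), and a 33-sample multi-stress panel (co-expression needs ≥ 15
samples) with 3 modules of 30 structural targets and 5 regulators each,
one planted repressor among them. Baseline means are drawn **per locus**
so both homoeologs of an unbiased pair are equal in expectation; planted
DEGs go on singleton loci so DE and bias plants never collide. Module
latent profiles are orthogonalized (QR) so the planted stress axes are
uncorrelated by construction. The scale-free profile generator instead
drives all genes by one latent axis with Pareto-tailed loadings, giving a
power-law connectivity distribution for soft-threshold validation.

Not emulated: read-level artifacts (FASTQ, alignment, multi-mapping between
homoeologs — a real difficulty for homoeolog-specific quantification),
isoforms, batch effects across the public stress panels, GC/length biases,
and correlated noise between conditions. Passing planted-truth tests
therefore demonstrates the statistical machinery is correct under the
declared generative model, not that real-data preprocessing issues are
solved.

## Problem sizes

Test-suite and acceptance-script simulations use the study-scale defaults
(205 genes, 6 samples; 220-gene, 33-sample panels; 2000-gene null matrices
for calibration), which the full pipeline processes in under a second on
one CPU; these sizes were chosen as the natural desk-scale of the design
being emulated.
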