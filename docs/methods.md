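# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices and the known limitations of `strath2`.

## Stratified LD-score regression

**Model.** For SNP *j* with GWAS sample size *N*,
`E[χ²_j] = N Σ_C τ_C ℓ(j,C) + N·a + 1`, where the LD score
`ℓ(j,C) = Σ_{k∈C, |pos_k−pos_j|≤w, same chrom} r²_jk` includes the self
term when *j* ∈ *C*. The coefficients τ_C are per-SNP heritability
contributions; the free intercept `1 + N·a` absorbs confounding inflation.

**LD scores.** The physical window *w* defaults to 1 Mb. This is a fixed,
desk-scale stand-in for genetic-map-based windows (≈1 cM), which would need
a recombination map the package deliberately does not model; it is
configurable. With `adjust=True` (default) each r² is replaced by the
finite-sample-unbiased `r² − (1−r²)/(n−2)`; the self term r² = 1 is a fixed
point of the adjustment. The engine computes standardized-genotype inner
products in column chunks restricted to the window and is verified against
an O(m²) double loop to 1e−10.

**Estimation.** Weighted least squares of χ² on {N·ℓ(j,C)} plus an
intercept. The default `ldsc_weights` are the two-pass heteroskedasticity ×
LD-overcounting weights `1/(max(ℓ_tot,1) · 2·ŷ²)` with ŷ the first-pass OLS
fit floored at 1; `ols` (unit weights) is exposed and the results record
which was used. Standard errors come from a delete-one block jackknife over
200 contiguous equal-count SNP blocks (default; configurable), implemented
via per-block normal-equation moments so a fit costs one pass over the
data. The coefficient p-value is the upper normal tail of τ̂/SE — one-tailed
because only positive heritability contributions are of interest. Bonferroni
significance uses α/(n_traits × n_categories), supplied per analysis family,
never inferred.

**Collinearity.** The design is checked by SVD of the column-normalized
weighted design; a condition number above 1e10 raises an error naming the
categories that span the null space (an exact duplicate category is the
canonical trigger). Note that a single all-SNPs category on an
equal-correlation panel has a nearly constant LD score and is then
legitimately reported as collinear with the intercept — baselines should
carry LD-score variation, as real baselines do.

**Partitioning.** Per-SNP variance is `Σ_{C∋j} τ̂_C`; `h²(C)` sums it over
members, `enrichment(C) = (h²(C)/h²_tot)/(|C|/m)`. A non-positive total h²
is flagged and enrichment reported missing rather than signed nonsense.

## Annotation construction

* **Tissue specificity** is a Welch two-sample t-statistic of a gene's
  expression in a tissue's samples versus samples of all tissues outside
  that tissue's category (the exclusion map is an input). Welch was chosen
  because the group sizes are unequal by construction; zero-variance
  degenerate genes are flagged missing (NaN), never ±∞.
* **Top-fraction selection** takes the `ceil(fraction·n)` highest scores
  with ties at the cutoff broken by lexicographic gene id, making the
  selection deterministic. Default fraction 0.1.
* **Window expansion**: a SNP is annotated iff it lies within ±100 kb
  (default) of the transcribed region of at least one selected gene,
  strand-independent; overlapping windows count once. Inputs are 1-based
  inclusive; interval arithmetic is 0-based half-open internally, and BED
  exports are 0-based half-open per that standard. Variants are pre-filtered
  to MAF > 0.05 and the MHC (chr6:25,500,000–33,500,000, GRCh37) is
  excluded everywhere, those being the only MHC coordinates in use.
* **Cell-type fold enrichment** divides a gene's expression in one cell
  type by its mean across the others, after a detection filter
  (`fpkm_ge_1` for bulk-style data, `gt_0` for cluster-aggregated
  single-cell data). A pseudocount ε = 1e−9 in the denominator lets genes
  expressed exclusively in one cell type rank above any finite competitor
  instead of erroring.
* **eQTL assignment**: per-tissue Benjamini–Hochberg at FDR < 5% (BH is the
  field default; the method is configurable at the reader level), then,
  within each supergroup (e.g. brain regions), records sharing a SNP
  collapse to the maximum |slope| — the collapse key is the SNP, not the
  SNP–gene pair, because the downstream annotation is a SNP set. Each SNP
  is then assigned to the group with the largest collapsed |slope|; ties go
  to the lexicographically first group with a logged warning, and a slope
  of exactly 0 loses every tie. Raw (unnormalized) absolute slopes are
  compared.
* **Module labeling**: for each (module, cell class) an upper-tail
  hypergeometric p of the marker overlap given the gene universe;
  "predominantly one cell type" is operationalized strictly as the unique
  class with Bonferroni-corrected p < 0.05 across the classes tested for
  that module — two significant classes leave the module unlabeled. Genes
  feed cell-type annotations only with module membership (kME) ≥ 0.5 from
  modules with preservation Z > 2.
* **Ortholog mapping** keeps one-to-one pairs only; one-to-many and
  many-to-one pairs are dropped with a logged reason and unmapped genes are
  reported, never silently discarded.

## EWCE

Specificity `s(g,c)` is the proportion of gene *g*'s total expression in
cell type *c* (rows sum to 1; zero-total genes are dropped and reported).
The statistic for a target list is its mean specificity per cell type. The
null is `n_boot` random lists of the same size (default 100,000); with
covariate matching each bootstrap gene is drawn from the same joint decile
bin of (transcript length, GC fraction) as the corresponding target gene —
per-gene binning on a 10×10 grid, falling back to the gene's length-decile
marginal bin if a joint bin is empty (logged). The p-value uses the
(1+k)/(1+B) bootstrap convention, so p ≥ 1/(B+1) and never exactly 0.
Standard deviations from the bootstrap mean are floored at 0 for reporting
(negative values reflect depletion, which is not the question being asked);
the raw value is kept in the results table. BH correction spans all
(gene set × cell type) pairs of one run — per run, not across runs. A
target list overlapping the expression universe below 10% is rejected as a
gene-id namespace mismatch (map orthologs upstream). The combined
susceptibility-gene list for follow-up enrichment is the symmetric
difference of the gene-level-association hits and the TWAS/coloc list —
genes found by both routes are removed.

## Gene-level association

Strand-aware gene windows add 35 kb upstream and 10 kb downstream of the
transcript (mirrored on the − strand), clipped at position 1; genes
overlapping the MHC are dropped, and only genes with ≥1 mapped SNP are
tested. The statistic is the mean χ² of mapped SNPs. Under the null with
LD-correlated Z-scores, m·T = zᵀz with z ~ N(0, R), distributed as
Σ λᵢ χ²₁ with λ the eigenvalues of the window's SNP correlation matrix,
estimated from the reference panel (negative eigenvalues below −1e−8 of
the largest raise an error naming the window; small negatives are
clipped). The tail probability comes from Imhof's inversion integral.
Because the integrand oscillates with asymptotic period 4π/x and decays
only algebraically, it is integrated by 24-point Gauss–Legendre over
half-period segments (subdivided while the arctan phase still bends), and
the alternating segment series is summed by iterated averaging of partial
sums (an Euler transformation). The result matches χ² closed forms at
identity correlation to ~1e−15 and a 200,000-draw Monte-Carlo null within
sampling error. If the integral misbehaves, a Satterthwaite moment-matched
scaled-χ² fallback is used and logged, and affected genes are listed on the
results object. Genome-wide significance is α/n_genes_tested.

## Synthetic data

The generators define the study conditions for every calibration result
the package reports.

* **LD panel**: blockwise-exchangeable LD — one correlation ρ per block, no
  distance decay — keeps closed-form expectations available while fully
  exercising the windowed ℓ(j,C) computation. Each haplotype carries one
  template allele per block; every variant copies it with probability √ρ,
  otherwise draws fresh at the block's MAF, giving expected genotype
  correlation exactly ρ within a block (thresholded-Gaussian marginals
  would attenuate it). Variants within a block share a MAF drawn uniformly
  from `maf_range`; realized MAFs vary by sampling. SNPs are 1 kb apart
  within a block and blocks 2 Mb apart, so a 1 Mb window resolves blocks.
  Monomorphic variants are dropped and logged (the downstream MAF filter
  would remove them anyway). At ρ = 0 the mean within-block r² sits at the
  finite-sample null 1/(n−1); at ρ = 0.9, n = 2000 it calibrates to 0.81.
* **Summary statistics**: χ²_j is an independent squared Gaussian scaled to
  the stratified expectation — exact in expectation and sufficient because
  the regression consumes only χ². A per-SNP expectation above 100 is
  rejected as implausible inflation (catching mis-scaled N·a). The optional
  `ld_correlated` mode draws Z jointly per block with the panel's realised
  correlation; it exists for the gene-level null calibration, whose
  weighted-χ² null presumes LD-correlated Z.
* **Expression**: log-normal baseline per gene, markers multiplied by
  `fold` in their own group only, multiplicative log-normal noise.
  Transcript lengths are log-normal with median 2.5 kb (σ = 0.6) and GC
  fractions Beta(5,5) — plausible scales, recorded in the fixture so
  covariate matching is testable. With fold = 3 and noise 0.5 the
  top-decile marker recovery calibrates to 0.67 on average (minimum 0.57
  over 20 seeds); the frozen test bound is ≥ 0.5.
* **eQTL tables**: planted associations get log₁₀p ~ U(−12, −6); filler
  rows with p ~ U(0,1) are sampled from the SNP × gene universe, the
  `null_p_fraction` parameter being the fraction of that universe sampled
  per tissue.

What the fixtures do **not** emulate: distance-decaying LD, recombination
maps, HapMap3-like SNP density, phenotype-level sampling noise in N,
mouse/human expression divergence, or dependence between eQTL tissues.
Passing calibrations therefore demonstrate correctness of the estimators
under the stated generative model, not robustness to every feature of real
consortium data.

## Simulation study sizes

The calibration study uses a 5,000-SNP panel (50 blocks × 100 SNPs,
ρ = 0.5, 500 individuals), a two-category baseline (all SNPs; even blocks)
plus a 10%-of-SNPs test category, N = 50,000 and
τ = (2×10⁻⁷, 1×10⁻⁷, 4×10⁻⁶): the enriched category contributes ≈0.65
expected χ² units per member SNP, chosen so that a single replicate detects
it at ≈4–5 coefficient SDs. Recovery runs 100 replicates (one shared panel
and LD-score table, as GWAS replicates share a reference panel), the type-I
study 1,000; EWCE calibration uses 2,000 genes × 4 cell types with 200 null
draws at 1,000 bootstraps and planted recovery at 10,000; the gene-level
null uses 500 one-block genes. Measured before the seeds were frozen: mean
τ̂ within ~2–5% of truth, CI coverage 0.92–0.98, type-I rate 0.0475 at
4,000 replicates.

## Known limitations

* Continuous-valued annotations, cM windows, cross-trait genetic
  correlation and conditional/gene-set association variants are out of
  scope.
* The jackknife assumes approximate independence across SNP blocks; the
  default independent-χ² generator satisfies it exactly, real data only
  approximately.
* The tissue-specificity t-statistic carries no covariates; it is a stated
  stand-in where the upstream literature does not publish a formula.
* EWCE covariate matching is per-gene (each bootstrap gene matches its
  target gene's bin), one of two defensible readings of "comparable
  properties"; per-list aggregate matching is not implemented.
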