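# strath2 — cell-type-resolved partitioned SNP heritability

`strath2` asks *where in the genome, and in which tissues and cell types,
the heritability of a complex trait concentrates*. It is aimed at
statistical geneticists who have GWAS summary statistics and gene-level
evidence of tissue- or cell-type-specific activity (bulk expression,
single-cell atlases, eQTL tables, co-expression modules, curated gene sets)
and want to turn that evidence into SNP-level annotations, test them with
stratified LD-score regression, and follow up with expression-weighted
cell-type enrichment (EWCE) of gene lists and LD-aware gene-level
association.

## The model

Under a stratified additive architecture, each annotation category *C*
contributes τ<sub>C</sub> per-SNP heritability, and the expected GWAS
χ² of SNP *j* is

```
E[χ²_j] = N · Σ_C τ_C · ℓ(j, C) + N·a + 1
```

where `ℓ(j, C) = Σ_{k∈C} r²_jk` is the LD score of SNP *j* with respect to
category *C* (summed within a physical window on the same chromosome),
*N* is the GWAS sample size and `1 + N·a` the intercept absorbing
confounding inflation. Regressing χ² on the per-category LD scores gives
coefficient estimates τ̂<sub>C</sub> with delete-one block-jackknife
standard errors; a category contributes positively to heritability when
its one-tailed coefficient p-value (upper normal tail of τ̂/SE) is small.
Bonferroni correction is applied over traits × categories — for 2 traits
and 53 baseline categories the cutoff is 0.05/(2×53) = 4.72×10⁻⁴.

Around that core the package provides:

* **Annotation builders** — tissue-specificity t-statistics, cell-type
  fold-enrichment, top-10% selection, ±100 kb window expansion to binary
  SNP annotations (MAF > 5%, MHC chr6:25.5–33.5 Mb excluded), FDR<5%
  eQTL collapse with max-|slope| tissue assignment, hypergeometric
  cell-type labeling of co-expression modules (kME ≥ 0.5, preservation
  Z > 2), and one-to-one ortholog mapping.
* **EWCE** — a gene's specificity in a cell type is its proportion of
  total expression there; a target list's mean specificity is compared
  against bootstrap lists matched on transcript length and GC deciles,
  with p = (1+k)/(1+B) and BH correction over all gene sets × cell types.
* **Gene-level association** — mean χ² over SNPs in strand-aware 35/10 kb
  gene windows, tested against the weighted-χ² null
  `Σ λ_i χ²₁` (λ = eigenvalues of the window's LD matrix) by exact
  Imhof integration.
* **Synthetic data** — blockwise-LD genotype panels, χ² statistics with
  known stratified structure, expression matrices with planted markers
  and eQTL tables, so the whole pipeline is testable without consortium
  downloads.

## Worked example

Simulate a 5,000-SNP panel (50 LD blocks of 100 SNPs, within-block
correlation 0.5), plant an enriched 10%-of-SNPs category with
τ = 4×10⁻⁶ on top of a two-category baseline, and fit:

```python
import numpy as np
from strath2 import (AnnotationMatrix, SimTruth, StratifiedLDSC,
                     compute_ld_scores, simulate_ld_panel, simulate_sumstats)

panel = simulate_ld_panel(n_individuals=500, n_blocks=50, block_size=100,
                          rho=0.5, seed=11)
m = panel.n_variants
rng = np.random.default_rng(7)
annot = AnnotationMatrix.from_columns(panel.variants, {
    "all_snps": np.ones(m, dtype=int),
    "even_blocks": (panel.block_index % 2 == 0).astype(int),
    "enriched": (rng.random(m) < 0.1).astype(int),
})
ld_scores = compute_ld_scores(panel, annot)

truth = SimTruth(tau=[2e-7, 1e-7, 4e-6], intercept_inflation=0.0,
                 n_gwas=50_000, seed=1)
sumstats = simulate_sumstats(panel, annot, truth, ldscores=ld_scores)

results = StratifiedLDSC.from_tables(sumstats, ld_scores).fit()
print(results.summary())
```

prints

```
Stratified LD-score regression
  SNPs: 5000   jackknife blocks: 200   weighting: ldsc_weights
  intercept: 0.9555 (SE 0.3044)

                  tau        se      z  coefficient_p
all_snps    1.963e-07 2.618e-07 0.7498         0.2267
even_blocks 8.074e-08 5.701e-08  1.416        0.07836
enriched    4.513e-06 9.369e-07  4.817      7.279e-07
```

The enriched category's coefficient lands within one jackknife SE of the
planted τ = 4×10⁻⁶ and is the only one significant at the 2×53 Bonferroni
cutoff; `results.partition(annot)` reports its heritability enrichment
(6.9× for 10% of SNPs here). The EWCE arm behaves the same way on planted
markers:

```python
from strath2 import EWCE, simulate_expression
fx = simulate_expression(2000, ["neuron", "microglia", "astrocyte",
                                "oligodendrocyte"],
                         markers_per_group=50, fold=5.0, noise_sd=0.3, seed=3)
model = EWCE.from_expression(fx.expr, fx.gene_meta)
res = model.test(fx.planted_markers["microglia"][:25], n_boot=10_000,
                 matching="length_gc_bins", seed=0,
                 gene_set_name="planted_microglia")
print(res.summary())
```

```
EWCE bootstrap enrichment (10000 bootstrap lists, matching=length_gc_bins)
         gene_set       cell_type  observed  boot_mean  sd_from_mean         p      q
planted_microglia          neuron    0.1434     0.2465             0         1      1
planted_microglia       microglia    0.6155     0.2727         14.42 9.999e-05 0.0004
planted_microglia       astrocyte    0.1168     0.2432             0         1      1
planted_microglia oligodendrocyte    0.1243     0.2376             0         1      1
```

The planted cell type sits 14 bootstrap SDs above its matched null
(depleted cell types are floored at 0, as depletion is not reported).

A `strath2` command-line tool wraps the same library for shell use
(`simulate`, `build-annot`, `ldscore`, `ldsc`, `ewce`, `magma-lite`,
`report`); run `strath2 --help`.

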