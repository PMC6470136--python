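"""Synthetic fixtures: LD panels, GWAS summary statistics with known
stratified-heritability structure, expression matrices with planted cell-type
markers, and eQTL association tables.

The generators stand in for the consortium resources a real analysis would
use (a European LD reference panel, bulk/single-cell expression atlases and
per-tissue eQTL calls) so that every downstream stage — annotation building,
stratified LD-score regression, EWCE and gene-level association — is testable
without downloads.

Design notes
------------
* LD is blockwise-exchangeable: one correlation ``rho`` per block, no distance
  decay. Haplotypes copy a per-block template allele with probability
  ``sqrt(rho)`` so the expected genotype correlation within a block is exactly
  ``rho``; variants within a block share one MAF drawn from ``maf_range``.
* Chi-square statistics are generated as squared Gaussians whose per-SNP
  scale matches the stratified expectation
  ``E[chi2_j] = N * sum_C tau_C * ell(j,C) + N*a + 1``; the regression
  consumes only chi-square values, so no phenotypes are simulated.
* Gene transcript lengths are log-normal (median 2.5 kb) and GC fractions
  Beta(5, 5); both are recorded in the fixture so covariate-matched
  bootstrapping is testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AnnotationMatrix, GeneTable, LdPanel, SumStats, VariantTable
from .exceptions import (
    AlignmentError,
    ConfigurationError,
    InputReferenceError,
)

logger = logging.getLogger(__name__)

#: A generated per-SNP chi-square expectation above this is rejected as
#: implausible inflation (a mis-specified N*a term, typically).
MAX_EXPECTED_CHI2 = 100.0


@dataclass
class SimTruth:
    """Ground truth of a simulated GWAS.

    ``tau`` holds the per-category heritability coefficients (per-SNP variance
    units), ``intercept_inflation`` the ``a`` of the intercept ``1 + N*a``,
    ``n_gwas`` the GWAS sample size.
    """

    tau: np.ndarray
    intercept_inflation: float
    n_gwas: float
    seed: int

    def __post_init__(self) -> None:
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if self.n_gwas <= 0:
            raise ConfigurationError("n_gwas must be positive")


@dataclass
class ExpressionFixture:
    """Gene x group mean expression with planted group-specific markers.

    ``gene_meta`` records transcript length (bp) and GC fraction for every
    gene; ``planted_markers`` maps each group to the gene ids planted as
    specifically expressed there (disjoint across groups by construction).
    """

    expr: pd.DataFrame
    gene_meta: pd.DataFrame
    planted_markers: dict[str, list[str]]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.expr.to_numpy() < 0).any():
            raise ConfigurationError("expression must be nonnegative")
        seen: set[str] = set()
        for group, genes in self.planted_markers.items():
            overlap = seen.intersection(genes)
            if overlap:
                raise ConfigurationError(
                    f"markers not disjoint across groups: {sorted(overlap)[:3]}"
                )
            seen.update(genes)
        missing = self.expr.index.difference(self.gene_meta.index)
        if len(missing):
            raise ConfigurationError(
                f"gene_meta does not cover {len(missing)} genes"
            )
        gc = self.gene_meta["gc"].to_numpy(float)
        if np.any((gc < 0) | (gc > 1)):
            raise ConfigurationError("GC fraction must lie in [0, 1]")


def simulate_ld_panel(
    n_individuals: int,
    n_blocks: int,
    block_size: int,
    rho: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    chrom: int = 1,
    block_gap_bp: int = 2_000_000,
    snp_spacing_bp: int = 1_000,
) -> LdPanel:
    """Simulate a diploid genotype panel with blockwise-exchangeable LD.

    Each haplotype carries a per-block template; every variant in the block
    copies the template allele with probability ``sqrt(rho)`` and otherwise
    draws a fresh allele at the block's MAF, giving expected pairwise genotype
    correlation ``rho`` within a block and independence across blocks.
    Monomorphic variants are dropped (and logged). Positions are strictly
    increasing: SNPs ``snp_spacing_bp`` apart within a block and blocks
    separated by ``block_gap_bp`` so blocks are resolvable by a physical
    LD window.
    """
    if n_individuals < 25:
        raise ConfigurationError("n_individuals must be >= 25")
    if block_size < 1:
        raise ConfigurationError("block_size must be >= 1")
    lo, hi = maf_range
    if not (0 < lo < hi <= 0.5):
        raise ConfigurationError(f"degenerate maf_range {maf_range}")
    if not (0 <= rho < 1):
        raise ConfigurationError("rho must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    n_hap = 2 * n_individuals
    copy_p = np.sqrt(rho)
    m = n_blocks * block_size

    genotypes = np.empty((n_individuals, m), dtype=np.int8)
    block_index = np.repeat(np.arange(n_blocks), block_size)
    positions = np.empty(m, dtype=np.int64)
    block_maf = rng.uniform(lo, hi, size=n_blocks)

    for b in range(n_blocks):
        p = block_maf[b]
        template = rng.random(n_hap) < p  # one template allele per haplotype
        fresh = rng.random((n_hap, block_size)) < p
        copies = rng.random((n_hap, block_size)) < copy_p
        hap = np.where(copies, template[:, None], fresh)
        sl = slice(b * block_size, (b + 1) * block_size)
        genotypes[:, sl] = (
            hap[:n_individuals].astype(np.int8) + hap[n_individuals:].astype(np.int8)
        )
        start = b * (block_size * snp_spacing_bp + block_gap_bp) + 1
        positions[sl] = start + np.arange(block_size) * snp_spacing_bp

    freqs = genotypes.mean(axis=0) / 2.0
    poly = (freqs > 0) & (freqs < 1)
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("dropped %d monomorphic simulated variants", n_dropped)
    genotypes = genotypes[:, poly]
    positions = positions[poly]
    block_index = block_index[poly]
    maf = np.minimum(freqs[poly], 1 - freqs[poly])

    variants = VariantTable(
        pd.DataFrame(
            {
                "snp": [f"rs{i + 1}" for i in range(poly.sum())],
                "chrom": chrom,
                "pos": positions,
                "a1": "A",
                "a2": "G",
                "maf": maf,
            }
        )
    )
    return LdPanel(genotypes, variants, block_index)


def _expected_chi2(
    ldscores: np.ndarray, truth: SimTruth
) -> np.ndarray:
    """Stratified expectation E[chi2_j] = N * sum_C tau_C ell(j,C) + N*a + 1."""
    n = truth.n_gwas
    mean = 1.0 + n * truth.intercept_inflation + n * (ldscores @ truth.tau)
    return mean


def simulate_sumstats(
    panel: LdPanel,
    annot: AnnotationMatrix,
    truth: SimTruth,
    ldscores=None,
    ld_window: int = 1_000_000,
    ld_correlated: bool = False,
    trait: str = "sim",
    max_expected_chi2: float = MAX_EXPECTED_CHI2,
) -> SumStats:
    """Draw per-SNP chi-square statistics under the stratified model.

    ``E[chi2_j] = N * sum_C tau_C * ell(j,C) + N*a + 1`` with LD scores
    computed from ``panel`` (or supplied precomputed via ``ldscores``; sharing
    one table between generator and estimator makes parameter recovery exact
    in expectation). By default each chi2 is an independent squared Gaussian
    with that per-SNP scale; with ``ld_correlated=True`` the underlying Z are
    drawn jointly per LD block with the panel's realised genotype correlation,
    as needed for LD-aware gene-level null calibration.
    """
    from .ldsc import compute_ld_scores  # local import to avoid a cycle

    if annot.variants.df["snp"].tolist() != panel.variants.df["snp"].tolist():
        raise AlignmentError("annotation and panel variant universes differ")
    if np.any(truth.tau < 0):
        raise ConfigurationError("tau entries must be nonnegative")
    if len(truth.tau) != len(annot.categories):
        raise ConfigurationError(
            f"tau has {len(truth.tau)} entries for "
            f"{len(annot.categories)} categories"
        )

    if ldscores is None:
        ldscores = compute_ld_scores(panel, annot, window=ld_window, adjust=True)
    ell = ldscores.scores.to_numpy(float)
    mean = _expected_chi2(ell, truth)
    if np.any(mean < 0):
        raise ConfigurationError("negative expected chi2; check tau/a")
    if mean.max() > max_expected_chi2:
        raise ConfigurationError(
            f"expected chi2 up to {mean.max():.1f} exceeds the plausibility "
            f"bound {max_expected_chi2}; check N*a and tau scales"
        )

    rng = np.random.default_rng(truth.seed)
    m = panel.n_variants
    if ld_correlated:
        z = np.empty(m)
        x = panel.standardized()
        for b in np.unique(panel.block_index):
            idx = np.flatnonzero(panel.block_index == b)
            xb = x[:, idx]
            corr = (xb.T @ xb) / panel.n_individuals
            corr = corr + 1e-8 * np.eye(len(idx))
            chol = np.linalg.cholesky(corr)
            z[idx] = chol @ rng.standard_normal(len(idx))
    else:
        z = rng.standard_normal(m)
    chi2 = mean * z**2
    return SumStats(
        snp=panel.variants.snp, chi2=chi2, n_gwas=truth.n_gwas, trait=trait
    )


def simulate_expression(
    n_genes: int,
    groups: list[str],
    markers_per_group: int,
    fold: float,
    noise_sd: float,
    seed: int = 0,
    length_sigma: float = 0.6,
) -> ExpressionFixture:
    """Simulate a gene x group mean-expression matrix with planted markers.

    Every gene has a log-normal baseline expression shared across groups;
    a planted marker is multiplied by ``fold`` in its own group only, and
    multiplicative log-normal noise of scale ``noise_sd`` is applied
    elementwise. Transcript lengths are log-normal with median 2.5 kb and GC
    fractions Beta(5, 5), both recorded in ``gene_meta``.
    """
    if fold <= 1:
        raise ConfigurationError("fold must exceed 1 (markers undetectable)")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be nonnegative")
    if markers_per_group * len(groups) > n_genes:
        raise ConfigurationError("more planted markers than genes")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    baseline = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)

    expr = np.tile(baseline[:, None], (1, len(groups)))
    planted: dict[str, list[str]] = {}
    perm = rng.permutation(n_genes)
    cursor = 0
    for gi, group in enumerate(groups):
        idx = perm[cursor : cursor + markers_per_group]
        cursor += markers_per_group
        expr[idx, gi] *= fold
        planted[group] = [gene_ids[i] for i in sorted(idx)]
    if noise_sd > 0:
        expr *= rng.lognormal(mean=0.0, sigma=noise_sd, size=expr.shape)

    lengths = rng.lognormal(mean=np.log(2500.0), sigma=length_sigma, size=n_genes)
    gc = rng.beta(5.0, 5.0, size=n_genes)
    gene_meta = pd.DataFrame(
        {"length_bp": lengths, "gc": gc}, index=pd.Index(gene_ids)
    )
    return ExpressionFixture(
        expr=pd.DataFrame(expr, index=pd.Index(gene_ids), columns=list(groups)),
        gene_meta=gene_meta,
        planted_markers=planted,
        params={
            "n_genes": n_genes,
            "markers_per_group": markers_per_group,
            "fold": fold,
            "noise_sd": noise_sd,
            "seed": seed,
            "length_family": f"lognormal(median=2500, sigma={length_sigma})",
            "gc_family": "beta(5, 5)",
        },
    )


def simulate_eqtl_tables(
    panel: LdPanel,
    genes: GeneTable,
    tissues: list[str],
    effect_plan: list[tuple[str, str, str, float]],
    null_p_fraction: float = 0.02,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Simulate per-tissue eQTL association tables (SNP, GENE, SLOPE, P).

    Each planted ``(snp, gene, tissue, slope)`` association appears in its
    tissue's table with a p-value drawn from a strong alternative
    (log10 p ~ Uniform(-12, -6)); filler rows with p ~ Uniform(0, 1) and
    small Gaussian slopes are sampled from the SNP x gene universe, with
    ``null_p_fraction`` the fraction of that universe sampled per tissue.
    """
    if not tissues:
        raise ConfigurationError("tissues must be non-empty")
    snp_universe = panel.variants.snp.tolist()
    gene_universe = genes.df["gene"].tolist()
    snp_set, gene_set = set(snp_universe), set(gene_universe)
    for snp, gene, tissue, slope in effect_plan:
        if snp not in snp_set:
            raise InputReferenceError(f"planted SNP {snp!r} not in panel")
        if gene not in gene_set:
            raise InputReferenceError(f"planted gene {gene!r} not in gene table")
        if tissue not in tissues:
            raise InputReferenceError(f"planted tissue {tissue!r} unknown")
        if not np.isfinite(slope):
            raise ConfigurationError("planted slopes must be finite")

    rng = np.random.default_rng(seed)
    n_pairs = len(snp_universe) * len(gene_universe)
    n_filler = int(round(null_p_fraction * n_pairs))

    tables: dict[str, pd.DataFrame] = {}
    for tissue in tissues:
        rows = []
        planted_pairs = set()
        for snp, gene, t, slope in effect_plan:
            if t != tissue:
                continue
            p = 10.0 ** rng.uniform(-12, -6)
            rows.append((snp, gene, slope, p))
            planted_pairs.add((snp, gene))
        if n_filler:
            flat = rng.choice(n_pairs, size=min(n_filler, n_pairs), replace=False)
            for k in flat:
                snp = snp_universe[k // len(gene_universe)]
                gene = gene_universe[k % len(gene_universe)]
                if (snp, gene) in planted_pairs:
                    continue
                rows.append(
                    (snp, gene, rng.normal(0.0, 0.3), rng.uniform(0.0, 1.0))
                )
        tables[tissue] = pd.DataFrame(
            rows, columns=["SNP", "GENE", "SLOPE", "P"]
        )
    return tables
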