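"""Core in-memory containers.

All containers are thin, validated wrappers around pandas/numpy objects so
that every downstream stage can rely on a checked contract:

* :class:`VariantTable` — the SNP universe (id, position, alleles, MAF).
* :class:`GeneTable` — gene coordinates (1-based inclusive transcript bounds).
* :class:`AnnotationMatrix` — binary SNP x category membership.
* :class:`LdPanel` — genotype dosages with an LD-block index.
* :class:`SumStats` — per-SNP chi-square statistics and GWAS sample size.
* :class:`LdScoreTable` — per-SNP, per-category LD scores plus the total
  LD score used for regression weighting.
* :class:`SpecificityMatrix` — gene x cell-type proportions of total
  expression with per-gene covariates (transcript length, GC fraction).

Coordinates are 1-based inclusive at the API boundary (GTF-like); interval
computations internally use 0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigurationError, DataError

#: MHC region excluded from all analyses (GRCh37), chr6:25.5-33.5 Mb.
MHC_REGION = (6, 25_500_000, 33_500_000)

VARIANT_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "maf"]
GENE_COLUMNS = ["gene", "chrom", "tx_start", "tx_end", "strand"]


@dataclass
class VariantTable:
    """SNP universe over which annotations and regressions are defined.

    ``df`` must have columns ``snp, chrom, pos, a1, a2, maf`` with unique
    snp ids, MAF in (0, 0.5] and rows sorted by (chrom, pos).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.df.columns]
        if missing:
            raise DataError(f"variant table missing columns: {missing}")
        df = self.df.reset_index(drop=True)
        if df["snp"].duplicated().any():
            dups = df.loc[df["snp"].duplicated(), "snp"].head(3).tolist()
            raise DataError(f"duplicate snp ids, e.g. {dups}")
        maf = df["maf"].to_numpy(float)
        if np.any(maf <= 0) or np.any(maf > 0.5):
            raise DataError("maf must lie in (0, 0.5]")
        order = df.sort_values(["chrom", "pos"], kind="mergesort").index
        if not np.array_equal(order.to_numpy(), np.arange(len(df))):
            raise DataError("variants must be sorted by (chrom, pos)")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp(self) -> pd.Series:
        return self.df["snp"]

    def maf_mask(self, maf_min: float = 0.05) -> np.ndarray:
        """Boolean mask of variants with MAF strictly above ``maf_min``."""
        return self.df["maf"].to_numpy(float) > maf_min

    def mhc_mask(self, region: tuple[int, int, int] = MHC_REGION) -> np.ndarray:
        """Boolean mask that is False for variants inside the MHC region."""
        chrom, start, end = region
        inside = (
            (self.df["chrom"].to_numpy() == chrom)
            & (self.df["pos"].to_numpy() >= start)
            & (self.df["pos"].to_numpy() <= end)
        )
        return ~inside

    def subset(self, mask: np.ndarray) -> "VariantTable":
        return VariantTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))


@dataclass
class GeneTable:
    """Gene coordinates: 1-based inclusive tx bounds, strand in {+,-}."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.df.columns]
        if missing:
            raise DataError(f"gene table missing columns: {missing}")
        df = self.df.reset_index(drop=True)
        if df["gene"].duplicated().any():
            raise DataError("duplicate gene ids in gene table")
        if (df["tx_start"] > df["tx_end"]).any():
            raise DataError("tx_start must be <= tx_end")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def subset_ids(self, gene_ids) -> "GeneTable":
        keep = self.df["gene"].isin(set(gene_ids))
        return GeneTable(self.df.loc[keep].reset_index(drop=True))


@dataclass
class AnnotationMatrix:
    """Binary SNP x category membership aligned positionally to a VariantTable.

    Each entry is 1 if the SNP is inside the annotation and 0 if not.
    """

    variants: VariantTable
    membership: pd.DataFrame  # index positional, columns = category labels

    def __post_init__(self) -> None:
        if len(self.membership) != len(self.variants):
            raise AlignmentError(
                f"membership has {len(self.membership)} rows but variant "
                f"table has {len(self.variants)}"
            )
        if self.membership.columns.duplicated().any():
            raise DataError("duplicate category labels")
        vals = self.membership.to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise DataError("annotation entries must be binary 0/1")
        self.membership = self.membership.astype(np.int8).reset_index(drop=True)

    @property
    def categories(self) -> list[str]:
        return list(self.membership.columns)

    def values(self) -> np.ndarray:
        return self.membership.to_numpy()

    def empty_categories(self) -> list[str]:
        counts = self.membership.sum(axis=0)
        return list(counts.index[counts == 0])

    def subset(self, mask: np.ndarray) -> "AnnotationMatrix":
        mask = np.asarray(mask)
        return AnnotationMatrix(
            self.variants.subset(mask),
            self.membership.loc[mask].reset_index(drop=True),
        )

    def add_column(self, label: str, column: np.ndarray) -> "AnnotationMatrix":
        if label in self.membership.columns:
            raise DataError(f"category label {label!r} already present")
        mem = self.membership.copy()
        mem[label] = np.asarray(column, dtype=np.int8)
        return AnnotationMatrix(self.variants, mem)

    @classmethod
    def from_columns(cls, variants: VariantTable, columns: dict) -> "AnnotationMatrix":
        mem = pd.DataFrame(
            {k: np.asarray(v, dtype=np.int8) for k, v in columns.items()}
        )
        return cls(variants, mem)


@dataclass
class LdPanel:
    """Reference genotype panel with blockwise LD structure.

    ``genotypes`` is an individuals x variants dosage matrix in {0,1,2};
    ``block_index`` labels each variant's LD block.
    """

    genotypes: np.ndarray
    variants: VariantTable
    block_index: np.ndarray
    n_individuals: int = field(init=False)

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if not np.isin(g, [0, 1, 2]).all():
            raise DataError("dosages must be in {0, 1, 2}")
        if g.shape[1] != len(self.variants):
            raise AlignmentError("genotype columns != number of variants")
        if len(self.block_index) != len(self.variants):
            raise AlignmentError("block index length != number of variants")
        freqs = g.mean(axis=0) / 2.0
        if np.any((freqs <= 0) | (freqs >= 1)):
            raise DataError("panel contains monomorphic variants")
        self.genotypes = g
        self.block_index = np.asarray(self.block_index)
        self.n_individuals = g.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def standardized(self) -> np.ndarray:
        """Genotypes centred and scaled to unit (population) variance."""
        g = self.genotypes.astype(float)
        mu = g.mean(axis=0)
        sd = g.std(axis=0)
        return (g - mu) / sd

    def block_correlation(self, block: int) -> np.ndarray:
        """Realised genotype correlation matrix of one LD block."""
        idx = np.flatnonzero(self.block_index == block)
        x = self.standardized()[:, idx]
        return (x.T @ x) / self.n_individuals

    def subset(self, mask: np.ndarray) -> "LdPanel":
        mask = np.asarray(mask)
        return LdPanel(
            self.genotypes[:, mask], self.variants.subset(mask), self.block_index[mask]
        )


@dataclass
class SumStats:
    """GWAS summary statistics for one trait: per-SNP chi-square and N."""

    snp: pd.Series
    chi2: np.ndarray
    n_gwas: np.ndarray  # per-SNP (constant vectors allowed)
    trait: str = "trait"

    def __post_init__(self) -> None:
        self.chi2 = np.asarray(self.chi2, dtype=float)
        self.n_gwas = np.broadcast_to(
            np.asarray(self.n_gwas, dtype=float), self.chi2.shape
        ).copy()
        if np.any(self.chi2 < 0):
            raise DataError("chi-square statistics must be nonnegative")
        if np.any(self.n_gwas <= 0):
            raise DataError("GWAS sample size must be positive")
        self.snp = pd.Series(self.snp).reset_index(drop=True)
        if len(self.snp) != len(self.chi2):
            raise AlignmentError("snp ids and chi2 have different lengths")

    def __len__(self) -> int:
        return len(self.chi2)

    @classmethod
    def from_z(cls, snp, z, n_gwas, trait="trait") -> "SumStats":
        z = np.asarray(z, dtype=float)
        return cls(snp=snp, chi2=z**2, n_gwas=n_gwas, trait=trait)


@dataclass
class LdScoreTable:
    """Per-SNP, per-category LD scores plus the total LD score for weighting."""

    snp: pd.Series
    scores: pd.DataFrame  # columns = category labels
    total: np.ndarray  # ell(j) over all panel SNPs, used for weights

    def __post_init__(self) -> None:
        self.snp = pd.Series(self.snp).reset_index(drop=True)
        self.scores = self.scores.reset_index(drop=True)
        self.total = np.asarray(self.total, dtype=float)
        if not (len(self.snp) == len(self.scores) == len(self.total)):
            raise AlignmentError("ld score table components misaligned")

    @property
    def categories(self) -> list[str]:
        return list(self.scores.columns)

    def __len__(self) -> int:
        return len(self.snp)


@dataclass
class SpecificityMatrix:
    """Gene x cell-type proportions of total expression.

    Rows sum to 1 (genes with zero total expression are excluded before
    normalisation); ``covariates`` carries per-gene transcript length (bp)
    and GC fraction for the covariate-matched bootstrap.
    """

    proportions: pd.DataFrame  # index = gene ids, columns = cell types
    covariates: pd.DataFrame | None = None  # columns: length_bp, gc
    dropped_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        p = self.proportions.to_numpy(float)
        if p.shape[1] < 2:
            raise ConfigurationError("need at least two cell types")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-9):
            raise DataError("specificity values must lie in [0, 1]")
        sums = p.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise DataError("specificity rows must sum to 1")
        if self.covariates is not None:
            missing = self.proportions.index.difference(self.covariates.index)
            if len(missing):
                raise DataError(
                    f"covariates missing for {len(missing)} genes, "
                    f"e.g. {list(missing[:3])}"
                )
            self.covariates = self.covariates.loc[self.proportions.index]

    @property
    def genes(self) -> pd.Index:
        return self.proportions.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.proportions.columns)
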