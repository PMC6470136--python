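"""Stratified LD-score regression.

The model: under a stratified additive architecture where each annotation
category C contributes tau_C per-SNP heritability, the expected GWAS
chi-square of SNP j is

    E[chi2_j] = N * sum_C tau_C * ell(j, C) + N*a + 1

with ell(j, C) = sum over SNPs k in C (within a physical window, same
chromosome) of r^2_jk, N the GWAS sample size and ``1 + N*a`` the regression
intercept capturing confounding inflation. Regressing chi2 on the per-category
LD scores yields coefficient estimates tau_hat with delete-one block-jackknife
standard errors; a category "positively contributes to trait heritability"
when its one-tailed coefficient p-value (upper normal tail of tau_hat / SE)
is small.

:class:`StratifiedLDSC` is the model object (data in, options at fit time);
:meth:`StratifiedLDSC.fit` returns a :class:`StratifiedLDSCResults` carrying
estimates, jackknife SEs, one-tailed p-values, the intercept and heritability
partitioning, with a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AnnotationMatrix, LdPanel, LdScoreTable, SumStats
from .exceptions import (
    AlignmentError,
    CollinearityError,
    ConfigurationError,
    EmptyCategoryError,
    NumericError,
)

logger = logging.getLogger(__name__)

DEFAULT_LD_WINDOW = 1_000_000
DEFAULT_N_BLOCKS = 200


# ---------------------------------------------------------------- LD scores


def compute_ld_scores(
    panel: LdPanel,
    annot: AnnotationMatrix,
    window: int = DEFAULT_LD_WINDOW,
    adjust: bool = True,
) -> LdScoreTable:
    """Per-SNP, per-category LD scores ell(j, C).

    ``ell(j, C)`` sums r^2 between SNP j and every SNP k in category C with
    ``|pos_k - pos_j| <= window`` on the same chromosome (including k = j
    when j is a member). With ``adjust`` each r^2 is replaced by the
    finite-sample-unbiased ``r^2 - (1 - r^2) / (n - 2)``; the self term
    (r^2 = 1) is unchanged by the adjustment. The returned table also carries
    the total LD score over all panel SNPs used for regression weighting.
    """
    if window <= 0:
        raise ConfigurationError("window must be positive")
    n = panel.n_individuals
    if adjust and n < 3:
        raise NumericError("adjusted r^2 needs at least 3 individuals")
    if annot.variants.snp.tolist() != panel.variants.snp.tolist():
        raise AlignmentError("panel and annotation variant universes differ")

    x = panel.standardized()
    mem = annot.values().astype(float)
    mem_all = np.ones((panel.n_variants, 1))
    m = panel.n_variants
    pos = panel.variants.df["pos"].to_numpy(np.int64)
    chrom = panel.variants.df["chrom"].to_numpy()

    scores = np.zeros((m, mem.shape[1]))
    total = np.zeros(m)
    chunk = 256
    for c in np.unique(chrom):
        cidx = np.flatnonzero(chrom == c)
        cpos = pos[cidx]
        lo_all = np.searchsorted(cpos, cpos - window, side="left")
        hi_all = np.searchsorted(cpos, cpos + window, side="right")
        for a in range(0, len(cidx), chunk):
            b = min(a + chunk, len(cidx))
            lo, hi = lo_all[a:b].min(), hi_all[a:b].max()
            cols = cidx[a:b]
            neigh = cidx[lo:hi]
            r = (x[:, cols].T @ x[:, neigh]) / n
            r2 = r**2
            if adjust:
                r2 = r2 - (1.0 - r2) / (n - 2)
            # zero out pairs outside the physical window
            dist = np.abs(cpos[a:b][:, None] - cpos[lo:hi][None, :])
            r2[dist > window] = 0.0
            scores[cols] += r2 @ mem[neigh]
            total[cols] += (r2 @ mem_all[neigh]).ravel()

    return LdScoreTable(
        snp=panel.variants.snp,
        scores=pd.DataFrame(scores, columns=annot.categories),
        total=total,
    )


def bonferroni_threshold(
    alpha: float, n_traits: int, n_categories: int
) -> float:
    """Bonferroni significance cutoff alpha / (n_traits x n_categories)."""
    if alpha <= 0 or n_traits <= 0 or n_categories <= 0:
        raise ConfigurationError("alpha and counts must be positive")
    return alpha / (n_traits * n_categories)


# ---------------------------------------------------------------- the model


def _check_collinearity(xw: np.ndarray, names: list[str]) -> None:
    """Raise CollinearityError naming the categories spanning the null space."""
    norms = np.linalg.norm(xw, axis=0)
    norms[norms == 0] = 1.0
    u, s, vt = np.linalg.svd(xw / norms, full_matrices=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-10:
        null_vec = np.abs(vt[-1])
        offenders = [
            names[i] for i in np.flatnonzero(null_vec > 0.1 * null_vec.max())
        ]
        raise CollinearityError(offenders)


class StratifiedLDSC:
    """Stratified LD-score regression model for one GWAS trait.

    Parameters
    ----------
    chi2 : array
        Per-SNP GWAS chi-square statistics (MAF > 5% and MHC exclusion are
        the annotation builder's responsibility and must be applied upstream).
    ld_scores : DataFrame
        Per-SNP, per-category LD scores; column order fixes category order.
    n_gwas : float or array
        GWAS sample size (scalar or per-SNP).
    total_ld : array, optional
        Total LD score per SNP, required for ``ldsc_weights`` weighting.
    """

    def __init__(self, chi2, ld_scores: pd.DataFrame, n_gwas, total_ld=None):
        self.chi2 = np.asarray(chi2, dtype=float)
        self.ld_scores = ld_scores.reset_index(drop=True)
        if len(self.ld_scores) != len(self.chi2):
            raise AlignmentError("chi2 and LD scores have different lengths")
        self.n_gwas = np.broadcast_to(
            np.asarray(n_gwas, dtype=float), self.chi2.shape
        )
        self.total_ld = None if total_ld is None else np.asarray(total_ld, float)
        empty = [
            c for c in self.ld_scores.columns if (self.ld_scores[c] == 0).all()
        ]
        if empty:
            raise EmptyCategoryError(
                f"categories with all-zero LD scores: {empty}"
            )

    @classmethod
    def from_tables(
        cls, sumstats: SumStats, ldscores: LdScoreTable
    ) -> "StratifiedLDSC":
        """Build from a SumStats and an LdScoreTable, aligning on SNP id."""
        if sumstats.snp.tolist() != ldscores.snp.tolist():
            lut = pd.Index(ldscores.snp)
            idx = lut.get_indexer(sumstats.snp)
            if (idx < 0).any():
                raise AlignmentError("sumstats SNPs missing from LD score table")
            return cls(
                sumstats.chi2,
                ldscores.scores.iloc[idx],
                sumstats.n_gwas,
                total_ld=ldscores.total[idx],
            )
        return cls(
            sumstats.chi2,
            ldscores.scores,
            sumstats.n_gwas,
            total_ld=ldscores.total,
        )

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        n_blocks: int = DEFAULT_N_BLOCKS,
        weighting: str = "ldsc_weights",
    ) -> "StratifiedLDSCResults":
        """Fit by (weighted) least squares with block-jackknife SEs.

        ``weighting='ldsc_weights'`` uses the two-pass heteroskedasticity and
        LD-overcounting weights ``1 / (max(ell_total, 1) * 2 * yhat^2)`` with
        ``yhat`` the first-pass OLS fit floored at 1; ``'ols'`` uses unit
        weights. Jackknife deletes ``n_blocks`` contiguous equal-count SNP
        blocks.
        """
        m = len(self.chi2)
        if n_blocks > m:
            raise ConfigurationError(
                f"n_blocks={n_blocks} exceeds number of SNPs {m}"
            )
        if n_blocks < 2:
            raise ConfigurationError("need at least 2 jackknife blocks")
        names = list(self.ld_scores.columns)
        x = np.column_stack(
            [self.n_gwas[:, None] * self.ld_scores.to_numpy(float), np.ones(m)]
        )
        y = self.chi2

        if weighting == "ldsc_weights":
            if self.total_ld is None:
                raise ConfigurationError(
                    "ldsc_weights requires the total LD score"
                )
            _check_collinearity(x, names + ["intercept"])
            beta0, *_ = np.linalg.lstsq(x, y, rcond=None)
            yhat = np.maximum(x @ beta0, 1.0)
            w = 1.0 / (np.maximum(self.total_ld, 1.0) * 2.0 * yhat**2)
        elif weighting == "ols":
            w = np.ones(m)
        else:
            raise ConfigurationError(f"unknown weighting {weighting!r}")

        sw = np.sqrt(w)
        xw = x * sw[:, None]
        yw = y * sw
        _check_collinearity(xw, names + ["intercept"])

        # block-wise normal-equation moments for cheap delete-one jackknife
        bounds = np.linspace(0, m, n_blocks + 1).astype(int)
        k = x.shape[1]
        xtx_b = np.empty((n_blocks, k, k))
        xty_b = np.empty((n_blocks, k))
        for i in range(n_blocks):
            sl = slice(bounds[i], bounds[i + 1])
            xtx_b[i] = xw[sl].T @ xw[sl]
            xty_b[i] = xw[sl].T @ yw[sl]
        xtx = xtx_b.sum(axis=0)
        xty = xty_b.sum(axis=0)
        try:
            beta = np.linalg.solve(xtx, xty)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise CollinearityError(names, str(exc)) from exc

        deletions = np.empty((n_blocks, k))
        for i in range(n_blocks):
            deletions[i] = np.linalg.solve(xtx - xtx_b[i], xty - xty_b[i])
        jk_mean = deletions.mean(axis=0)
        se = np.sqrt(
            (n_blocks - 1) / n_blocks
            * ((deletions - jk_mean) ** 2).sum(axis=0)
        )

        tau = pd.Series(beta[:-1], index=names, name="tau")
        tau_se = pd.Series(se[:-1], index=names, name="se")
        return StratifiedLDSCResults(
            model=self,
            tau=tau,
            tau_se=tau_se,
            intercept=float(beta[-1]),
            intercept_se=float(se[-1]),
            n_blocks=n_blocks,
            weighting=weighting,
            jackknife_deletions=pd.DataFrame(
                deletions, columns=names + ["intercept"]
            ),
        )


@dataclass
class StratifiedLDSCResults:
    """Estimates, jackknife uncertainty and partitioning for one fit."""

    model: StratifiedLDSC
    tau: pd.Series
    tau_se: pd.Series
    intercept: float
    intercept_se: float
    n_blocks: int
    weighting: str
    jackknife_deletions: pd.DataFrame

    @property
    def zvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return (self.tau / self.tau_se).rename("z")

    @property
    def pvalues_one_tailed(self) -> pd.Series:
        """Upper-tail normal probability of the coefficient z-score."""
        return pd.Series(
            stats.norm.sf(self.zvalues.to_numpy()),
            index=self.tau.index,
            name="coefficient_p",
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Normal-theory jackknife confidence intervals for tau."""
        zc = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.tau - zc * self.tau_se,
                "upper": self.tau + zc * self.tau_se,
            }
        )

    # -- partitioning -----------------------------------------------------

    def partition(self, annot: AnnotationMatrix) -> pd.DataFrame:
        """Per-category proportion of SNPs, of h2, and enrichment.

        The per-SNP variance is ``sum over categories containing the SNP of
        tau_hat``; ``h2(C)`` sums it over C's members. Enrichment is
        ``(h2(C) / h2_total) / (|C| / m)``. A non-positive total h2 is flagged
        degenerate and enrichment reported missing.
        """
        mem = annot.values().astype(float)
        cats = annot.categories
        if cats != list(self.tau.index):
            raise AlignmentError("annotation categories differ from fit")
        per_snp = mem @ self.tau.to_numpy()
        h2_total = float(per_snp.sum())
        m = mem.shape[0]
        rows = []
        for i, cat in enumerate(cats):
            members = mem[:, i] > 0
            h2_c = float(per_snp[members].sum())
            prop_snps = members.mean()
            if h2_total <= 0:
                enrich = np.nan
            else:
                enrich = (h2_c / h2_total) / prop_snps if prop_snps > 0 else np.nan
            rows.append((cat, prop_snps, h2_c, enrich))
        out = pd.DataFrame(
            rows, columns=["category", "prop_snps", "h2", "enrichment"]
        ).set_index("category")
        out["prop_h2"] = out["h2"] / h2_total if h2_total > 0 else np.nan
        if h2_total <= 0:
            logger.warning("total h2 <= 0; enrichment flagged degenerate")
        return out

    # -- presentation -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau": self.tau,
                "se": self.tau_se,
                "z": self.zvalues,
                "coefficient_p": self.pvalues_one_tailed,
            }
        )

    def summary(self) -> str:
        """Human-readable fit summary table."""
        frame = self.to_frame()
        lines = [
            "Stratified LD-score regression",
            f"  SNPs: {len(self.model.chi2)}   jackknife blocks: "
            f"{self.n_blocks}   weighting: {self.weighting}",
            f"  intercept: {self.intercept:.4f} "
            f"(SE {self.intercept_se:.4f})",
            "",
            frame.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def plot_coefficients(self, ax=None):
        """Coefficient z-scores per category as a horizontal bar chart."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.5 * len(self.tau) + 1))
        z = self.zvalues
        ax.barh(np.arange(len(z)), z.to_numpy(), color="#4477aa")
        ax.set_yticks(np.arange(len(z)), z.index)
        ax.set_xlabel("coefficient z-score")
        ax.axvline(0, color="k", lw=0.8)
        return ax
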