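"""Expression-weighted cell-type enrichment (EWCE).

A gene's *specificity* in a cell type is the proportion of its total
expression found in that cell type; rows of the specificity matrix sum to 1.
The EWCE statistic for a target gene list is its mean specificity per cell
type, compared against bootstrap lists of random genes of the same size,
optionally drawn so each bootstrap gene matches the corresponding target
gene's transcript-length and GC-content decile bin (controlling the two
covariates that bias gene sampling). Reported quantities per cell type:
observed mean specificity, bootstrap mean and SD, standard deviations from
the mean (floored at 0 for display — negative values reflect depletion),
the bootstrap p-value with the (1+k)/(1+B) convention, and a
Benjamini-Hochberg q over all gene sets and cell types tested in one run.

:class:`EWCE` is the model object (specificity + covariates);
:meth:`EWCE.test` / :meth:`EWCE.test_sets` return :class:`EWCEResult`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import SpecificityMatrix
from .exceptions import ConfigurationError, DataError, EmptyTargetError

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 100_000
DEFAULT_N_BINS = 10
#: targets overlapping the expression universe below this rate look like a
#: different gene-id namespace (e.g. unmapped mouse symbols) -> hard error.
NAMESPACE_OVERLAP_MIN = 0.10


def specificity_matrix(
    mean_expr: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> SpecificityMatrix:
    """Proportion-of-total-expression matrix from gene x cell-type means.

    ``s(g, c) = expr(g, c) / sum_c' expr(g, c')``; genes with zero total
    expression are dropped and reported on the returned object.
    """
    if mean_expr.shape[1] < 2:
        raise ConfigurationError("need at least two cell types")
    x = mean_expr.to_numpy(float)
    if (x < 0).any():
        raise DataError("expression must be nonnegative")
    totals = x.sum(axis=1)
    keep = totals > 0
    dropped = list(mean_expr.index[~keep])
    if dropped:
        logger.info("dropped %d zero-expression genes", len(dropped))
    props = x[keep] / totals[keep][:, None]
    cov = None
    if covariates is not None:
        cov = covariates.loc[mean_expr.index[keep]]
    return SpecificityMatrix(
        proportions=pd.DataFrame(
            props, index=mean_expr.index[keep], columns=mean_expr.columns
        ),
        covariates=cov,
        dropped_genes=dropped,
    )


def susceptibility_gene_list(magma_hits, twas_coloc) -> list[str]:
    """Merge two gene evidence sets, removing genes present in both.

    The combined susceptibility list is the symmetric difference (union minus
    intersection) of the gene-level-association hits and the TWAS/coloc
    prioritised genes. Identical inputs produce an empty list with a warning.
    """
    a, b = set(magma_hits), set(twas_coloc)
    out = sorted(a.symmetric_difference(b))
    if not out and (a or b):
        warnings.warn(
            "susceptibility list is empty: the two gene sets are identical",
            stacklevel=2,
        )
    return out


@dataclass
class EWCEResult:
    """Per cell-type bootstrap enrichment results for one or more gene sets."""

    table: pd.DataFrame  # gene_set, cell_type, observed, boot_mean, boot_sd,
    #                      sd_from_mean (floored), sd_from_mean_raw, p, q
    n_boot: int
    matching: str
    fallback_events: list = field(default_factory=list)

    def summary(self) -> str:
        cols = [
            "gene_set",
            "cell_type",
            "observed",
            "boot_mean",
            "sd_from_mean",
            "p",
            "q",
        ]
        lines = [
            f"EWCE bootstrap enrichment ({self.n_boot} bootstrap lists, "
            f"matching={self.matching})",
            self.table[cols].to_string(
                index=False, float_format=lambda v: f"{v:.4g}"
            ),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of standard deviations from the bootstrap mean."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        t = self.table
        xpos = np.arange(len(t))
        ax.bar(xpos, t["sd_from_mean"], color="#cc6677")
        ax.set_xticks(xpos)
        ax.set_xticklabels(
            [f"{gs}\n{ct}" for gs, ct in zip(t["gene_set"], t["cell_type"])],
            rotation=90,
            fontsize=7,
        )
        ax.set_ylabel("SD from bootstrap mean")
        return ax


class EWCE:
    """Bootstrap cell-type enrichment model over a specificity matrix."""

    def __init__(self, spec: SpecificityMatrix):
        self.spec = spec

    @classmethod
    def from_expression(
        cls, mean_expr: pd.DataFrame, covariates: pd.DataFrame | None = None
    ) -> "EWCE":
        return cls(specificity_matrix(mean_expr, covariates))

    # -- internals --------------------------------------------------------

    def _joint_bins(self, n_bins: int):
        """Joint (length, GC) quantile-bin id per gene, plus marginal ids."""
        cov = self.spec.covariates
        if cov is None:
            raise ConfigurationError(
                "covariate matching requested but no covariates supplied"
            )

        def _bin(values: np.ndarray) -> np.ndarray:
            qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
            return np.searchsorted(qs, values, side="right")

        lb = _bin(cov["length_bp"].to_numpy(float))
        gb = _bin(cov["gc"].to_numpy(float))
        return lb * n_bins + gb, lb

    def _resolve_target(self, target) -> np.ndarray:
        target = list(dict.fromkeys(target))  # dedupe, keep order
        if not target:
            raise EmptyTargetError("empty target gene list")
        genes = self.spec.genes
        present = [g for g in target if g in genes]
        overlap_rate = len(present) / len(target)
        if overlap_rate < NAMESPACE_OVERLAP_MIN:
            raise DataError(
                f"only {overlap_rate:.0%} of target genes found in the "
                "expression universe; gene-id namespaces likely differ "
                "(map orthologs upstream)"
            )
        if not present:
            raise EmptyTargetError("no target gene present in specificity matrix")
        absent = sorted(set(target) - set(present))
        if absent:
            logger.info(
                "%d target genes absent from specificity matrix, e.g. %s",
                len(absent),
                absent[:3],
            )
        return genes.get_indexer(present)

    # -- tests ------------------------------------------------------------

    def test(
        self,
        target,
        n_boot: int = DEFAULT_N_BOOT,
        matching: str = "length_gc_bins",
        n_bins: int = DEFAULT_N_BINS,
        seed: int = 0,
        gene_set_name: str = "target",
        _adjust: bool = True,
    ) -> EWCEResult:
        """Bootstrap test of one target list against random gene lists.

        With ``matching='length_gc_bins'`` each bootstrap gene is drawn from
        the same joint (length, GC) decile bin as the corresponding target
        gene, falling back to the gene's length-decile marginal bin if the
        joint bin is empty (logged). ``p = (1 + #{boot >= observed}) /
        (1 + n_boot)`` so p is never exactly 0. Deterministic given ``seed``.
        """
        if n_boot < 100:
            raise ConfigurationError("n_boot must be at least 100")
        if matching not in ("none", "length_gc_bins"):
            raise ConfigurationError(f"unknown matching {matching!r}")
        rng = np.random.default_rng(seed)
        s = self.spec.proportions.to_numpy(float)
        n_genes = s.shape[0]
        tidx = self._resolve_target(target)
        fallback_events: list = []

        if matching == "length_gc_bins":
            joint, lb = self._joint_bins(n_bins)
            pools: dict[int, np.ndarray] = {}
            target_pools = []
            for g in tidx:
                b = joint[g]
                if b not in pools:
                    pools[b] = np.flatnonzero(joint == b)
                pool = pools[b]
                if len(pool) == 0:  # pragma: no cover - joint bin holds g
                    pool = np.flatnonzero(lb == lb[g])
                    fallback_events.append(
                        ("marginal_bin_fallback", self.spec.genes[g])
                    )
                    logger.warning(
                        "joint bin empty for %s; fell back to length bin",
                        self.spec.genes[g],
                    )
                target_pools.append(pool)
        else:
            all_genes = np.arange(n_genes)
            target_pools = [all_genes] * len(tidx)

        boot_sum = np.zeros((n_boot, s.shape[1]))
        for pool in target_pools:
            draws = pool[rng.integers(0, len(pool), size=n_boot)]
            boot_sum += s[draws]
        boot = boot_sum / len(tidx)

        observed = s[tidx].mean(axis=0)
        boot_mean = boot.mean(axis=0)
        boot_sd = boot.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            sd_raw = (observed - boot_mean) / boot_sd
        p = (1 + (boot >= observed[None, :]).sum(axis=0)) / (1 + n_boot)

        table = pd.DataFrame(
            {
                "gene_set": gene_set_name,
                "cell_type": self.spec.cell_types,
                "observed": observed,
                "boot_mean": boot_mean,
                "boot_sd": boot_sd,
                "sd_from_mean_raw": sd_raw,
                "sd_from_mean": np.maximum(sd_raw, 0.0),
                "p": p,
            }
        )
        if _adjust:
            table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        return EWCEResult(
            table=table,
            n_boot=n_boot,
            matching=matching,
            fallback_events=fallback_events,
        )

    def test_sets(
        self,
        gene_sets: dict,
        n_boot: int = DEFAULT_N_BOOT,
        matching: str = "length_gc_bins",
        n_bins: int = DEFAULT_N_BINS,
        seed: int = 0,
    ) -> EWCEResult:
        """Run several gene sets; BH-adjust jointly over the full grid.

        The multiple-testing family is every (gene set x cell type) pair of
        this run, matching how enrichment grids are reported.
        """
        rng = np.random.default_rng(seed)
        parts, events = [], []
        for name in gene_sets:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            res = self.test(
                gene_sets[name],
                n_boot=n_boot,
                matching=matching,
                n_bins=n_bins,
                seed=sub_seed,
                gene_set_name=name,
                _adjust=False,
            )
            parts.append(res.table)
            events.extend(res.fallback_events)
        table = pd.concat(parts, ignore_index=True)
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        return EWCEResult(
            table=table, n_boot=n_boot, matching=matching, fallback_events=events
        )
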