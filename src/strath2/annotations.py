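"""Annotation construction: from expression, eQTLs, co-expression modules and
curated gene sets to binary SNP annotations.

The procedures implemented here turn gene-level evidence of tissue- or
cell-type-specific activity into SNP-level binary annotation categories:

* tissue specificity t-statistics (a tissue's samples versus all samples
  outside its tissue category) and top-fraction selection;
* cell-type fold-enrichment scores on mean-expression matrices;
* +/- 100 kb window expansion of gene sets to SNP annotations;
* FDR-filtered eQTL collapse and max-|slope| tissue assignment;
* hypergeometric cell-type labeling of co-expression modules with
  membership/preservation filters;
* one-to-one ortholog mapping of gene sets.

All outputs are deterministic, binary and reproducible bit-for-bit from the
inputs; the only stochastic code in the package lives in ``simulate`` and the
EWCE bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneTable, VariantTable
from .exceptions import (
    ConfigurationError,
    DataError,
    EmptyCategoryError,
)

logger = logging.getLogger(__name__)

EQTL_FDR_THRESHOLD = 0.05
MODULE_KME_MIN = 0.5
MODULE_PRESERVATION_MIN = 2.0
CELL_LABELS = ("neuron", "microglia", "astrocyte", "oligodendrocyte")


# ------------------------------------------------------- tissue specificity


def tissue_specificity_tstat(
    expr: pd.DataFrame,
    sample_tissues: pd.Series,
    tissue_categories: dict[str, str],
) -> pd.DataFrame:
    """Welch t-statistic of each gene's specific expression per tissue.

    ``expr`` is gene x sample; ``sample_tissues`` maps each sample (column)
    to its tissue; ``tissue_categories`` maps each tissue to a category used
    for exclusion — the comparison group for tissue ``t`` is every sample
    whose tissue lies *outside* ``t``'s category. Genes whose within- and
    between-group variances are both zero get NaN (flagged missing) rather
    than an infinite statistic.
    """
    sample_tissues = pd.Series(sample_tissues)
    if set(expr.columns) != set(sample_tissues.index):
        raise DataError("sample_tissues must cover exactly the expr columns")
    tissues = sorted(sample_tissues.unique())
    missing = [t for t in tissues if t not in tissue_categories]
    if missing:
        raise ConfigurationError(f"exclusion map missing tissues: {missing}")
    counts = sample_tissues.value_counts()
    few = counts[counts < 2]
    if len(few):
        raise ConfigurationError(
            f"every tissue needs >=2 samples; offenders: {list(few.index)}"
        )

    x = expr.to_numpy(float)
    out = pd.DataFrame(index=expr.index, columns=tissues, dtype=float)
    col_tissue = sample_tissues.loc[expr.columns].to_numpy()
    for t in tissues:
        own = col_tissue == t
        cat = tissue_categories[t]
        other = np.array(
            [tissue_categories[ct] != cat for ct in col_tissue]
        )
        if not other.any():
            raise ConfigurationError(
                f"exclusion set of tissue {t!r} removes all comparison tissues"
            )
        a, b = x[:, own], x[:, other]
        n1, n2 = a.shape[1], b.shape[1]
        m1, m2 = a.mean(axis=1), b.mean(axis=1)
        v1 = a.var(axis=1, ddof=1)
        v2 = b.var(axis=1, ddof=1)
        se2 = v1 / n1 + v2 / n2
        diff = m1 - m2
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = diff / np.sqrt(se2)
        t_stat = np.where((se2 == 0) & (diff == 0), 0.0, t_stat)
        t_stat = np.where((se2 == 0) & (diff != 0), np.nan, t_stat)
        out[t] = t_stat
    return out


def top_fraction_genes(scores: pd.Series, fraction: float = 0.1) -> list[str]:
    """The top ``ceil(fraction * n)`` genes by score.

    Ties at the cutoff are broken by lexicographic gene id, so selection is
    deterministic. Missing scores are excluded before ranking.
    """
    if not (0 < fraction <= 1):
        raise ConfigurationError("fraction must lie in (0, 1]")
    scores = pd.Series(scores).dropna()
    if scores.empty:
        raise DataError("all scores missing; nothing to rank")
    k = int(np.ceil(fraction * len(scores)))
    ranked = scores.to_frame("score")
    ranked["gene"] = ranked.index.astype(str)
    ranked = ranked.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    )
    return list(ranked.index[:k])


# ------------------------------------------------------- window expansion


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    """Merge possibly-overlapping half-open intervals; inputs get sorted."""
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [], []
    for s, e in zip(starts, ends):
        if merged_e and s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


def genes_to_snp_annotation(
    genes: GeneTable,
    variants: VariantTable,
    window: int = 100_000,
) -> np.ndarray:
    """Binary column: 1 iff the SNP lies within ``window`` bp of a gene body.

    A SNP is a member iff its position lies in
    ``[tx_start - window, tx_end + window]`` (1-based inclusive) on the same
    chromosome for at least one gene; overlapping windows count once
    (binary union). Strand is ignored — the window is symmetric.
    """
    member = np.zeros(len(variants), dtype=np.int8)
    vdf = variants.df
    for chrom, gsub in genes.df.groupby("chrom"):
        vmask = (vdf["chrom"] == chrom).to_numpy()
        if not vmask.any():
            continue
        # to 0-based half-open: [s-1, e), then expand by the window
        starts = np.maximum(gsub["tx_start"].to_numpy(np.int64) - 1 - window, 0)
        ends = gsub["tx_end"].to_numpy(np.int64) + window
        starts, ends = _merge_intervals(starts, ends)
        pos0 = vdf.loc[vmask, "pos"].to_numpy(np.int64) - 1
        # interval index whose start is at or left of the SNP
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        member[np.flatnonzero(vmask)[inside]] = 1
    return member


def build_geneset_annotation(
    gene_set,
    genes: GeneTable,
    variants: VariantTable,
    window: int = 100_000,
) -> tuple[np.ndarray, list[str]]:
    """SNP annotation for a curated gene set (100 kb windows by default).

    Returns the binary column and the list of gene ids that could not be
    resolved against the gene table (logged, never silently dropped).
    """
    gene_set = set(gene_set)
    known = set(genes.df["gene"])
    unresolved = sorted(gene_set - known)
    resolved = genes.subset_ids(gene_set & known)
    if unresolved:
        logger.warning(
            "%d gene-set ids unresolved against gene table, e.g. %s",
            len(unresolved),
            unresolved[:3],
        )
    if len(resolved) == 0:
        raise EmptyCategoryError("no gene-set members resolvable; empty category")
    return genes_to_snp_annotation(resolved, variants, window=window), unresolved


# ------------------------------------------------------- cell-type scores


def celltype_enrichment_scores(
    mean_expr: pd.DataFrame,
    detection_rule: str = "fpkm_ge_1",
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Fold enrichment of each gene in each cell type.

    ``enrichment(g, c) = expr(g, c) / (mean expression of g across all other
    cell types + eps)``. Genes failing the detection rule — ``fpkm_ge_1``
    (max expression >= 1, bulk-style) or ``gt_0`` (max > 0, single-cell
    style) — are dropped before scoring. The pseudocount ``eps`` makes genes
    expressed exclusively in one cell type rank above any finite competitor
    instead of erroring on a zero denominator.
    """
    if mean_expr.shape[1] < 2:
        raise ConfigurationError("need >=2 cell types for fold enrichment")
    if (mean_expr.to_numpy() < 0).any():
        raise DataError("expression must be nonnegative")
    x = mean_expr.to_numpy(float)
    if detection_rule == "fpkm_ge_1":
        keep = x.max(axis=1) >= 1.0
    elif detection_rule == "gt_0":
        keep = x.max(axis=1) > 0.0
    else:
        raise ConfigurationError(f"unknown detection rule {detection_rule!r}")
    x = x[keep]
    n_ct = x.shape[1]
    other_mean = (x.sum(axis=1, keepdims=True) - x) / (n_ct - 1)
    enrich = x / (other_mean + eps)
    return pd.DataFrame(
        enrich, index=mean_expr.index[keep], columns=mean_expr.columns
    )


# ------------------------------------------------------- ortholog mapping


def map_orthologs(
    genes, mapping: pd.DataFrame
) -> tuple[list[str], pd.DataFrame]:
    """Map a gene set through a two-column ortholog table, one-to-one only.

    One-to-many and many-to-one pairs are dropped from the mapping (logged);
    input genes without a surviving mapping are reported as unmapped with a
    reason, never silently dropped. Returns (mapped targets, unmapped report).
    """
    if mapping.empty:
        raise ConfigurationError("empty ortholog mapping")
    mapping = mapping.rename(
        columns=dict(zip(mapping.columns[:2], ["source", "target"]))
    )
    src_counts = mapping["source"].value_counts()
    tgt_counts = mapping["target"].value_counts()
    one2many = set(src_counts[src_counts > 1].index)
    many2one_targets = set(tgt_counts[tgt_counts > 1].index)
    clean = mapping[
        ~mapping["source"].isin(one2many)
        & ~mapping["target"].isin(many2one_targets)
    ]
    if len(clean) < len(mapping):
        logger.info(
            "dropped %d non-one-to-one ortholog pairs", len(mapping) - len(clean)
        )
    lut = dict(zip(clean["source"], clean["target"]))

    mapped, unmapped = [], []
    for g in sorted(set(genes)):
        if g in lut:
            mapped.append(lut[g])
        elif g in one2many:
            unmapped.append((g, "one-to-many"))
        else:
            unmapped.append((g, "absent-from-mapping"))
    report = pd.DataFrame(unmapped, columns=["gene", "reason"])
    return sorted(set(mapped)), report


# ------------------------------------------------------- eQTL assignment


def fdr_filter_eqtls(
    tables: dict[str, pd.DataFrame], q_threshold: float = EQTL_FDR_THRESHOLD
) -> pd.DataFrame:
    """Benjamini-Hochberg per tissue; keep records with q below threshold.

    Returns one long table with columns SNP, GENE, TISSUE, SLOPE, P, Q.
    """
    kept = []
    for tissue, table in tables.items():
        if table.empty:
            continue
        q = multipletests(table["P"].to_numpy(float), method="fdr_bh")[1]
        sub = table.assign(TISSUE=tissue, Q=q)
        kept.append(sub[sub["Q"] < q_threshold])
    if not kept:
        return pd.DataFrame(columns=["SNP", "GENE", "TISSUE", "SLOPE", "P", "Q"])
    out = pd.concat(kept, ignore_index=True)
    return out[["SNP", "GENE", "TISSUE", "SLOPE", "P", "Q"]]


def assign_eqtls_by_effect(
    records: pd.DataFrame,
    grouping: dict[str, str] | None = None,
) -> dict[str, set]:
    """Assign each eQTL SNP to one group by maximum absolute slope.

    ``records`` is the FDR-surviving long table from :func:`fdr_filter_eqtls`.
    Step 1: within each supergroup (``grouping`` maps tissue -> supergroup;
    identity when None), records sharing a SNP are collapsed to one entry
    keeping the maximum |slope|. Step 2: each SNP is assigned to the group
    where its collapsed |slope| is maximal. Ties go to the lexicographically
    first group with a logged warning. Output sets are disjoint and their
    union is the full collapsed SNP set.
    """
    if records.empty:
        return {}
    rec = records.copy()
    if grouping is None:
        rec["GROUP"] = rec["TISSUE"]
    else:
        unknown = set(rec["TISSUE"]) - set(grouping)
        if unknown:
            raise ConfigurationError(f"grouping missing tissues: {sorted(unknown)}")
        rec["GROUP"] = rec["TISSUE"].map(grouping)
    rec["ABS_SLOPE"] = rec["SLOPE"].abs()

    collapsed = (
        rec.groupby(["GROUP", "SNP"], as_index=False)["ABS_SLOPE"].max()
    )
    out: dict[str, set] = {g: set() for g in collapsed["GROUP"].unique()}
    for snp, sub in collapsed.groupby("SNP"):
        best = sub["ABS_SLOPE"].max()
        winners = sorted(sub.loc[sub["ABS_SLOPE"] == best, "GROUP"])
        if len(winners) > 1:
            logger.warning(
                "SNP %s ties on |slope|=%g across groups %s; "
                "assigned to %s",
                snp,
                best,
                winners,
                winners[0],
            )
        out[winners[0]].add(snp)
    return out


# ------------------------------------------------------- module labeling


@dataclass
class ModuleLabeling:
    """Cell-type labels for co-expression modules with hypergeometric p."""

    labels: dict[tuple, str | None]  # (module, tissue) -> label or None
    pvalues: pd.DataFrame  # columns: MODULE, TISSUE, CLASS, P, P_BONF
    celltype_genes: dict[str, set] = field(default_factory=dict)


def label_module_celltype(
    modules: pd.DataFrame,
    marker_lists: dict[str, set],
    universe: set,
    alpha: float = 0.05,
) -> ModuleLabeling:
    """Label modules by hypergeometric marker enrichment; filter genes.

    For every (module, cell class) pair the upper-tail hypergeometric p of
    the overlap between module genes and the class's marker list is computed
    given the universe size. A module is labeled with a class iff that class
    is the *unique* class with Bonferroni-corrected p < alpha across the
    classes tested for that module (the strictest reading of "predominantly
    one cell type"); otherwise it stays unlabeled.

    The returned ``celltype_genes`` maps each cell label to the genes of its
    labeled modules that pass both gene-level filters: module membership
    (kME) >= 0.5 and module preservation Z > 2.
    """
    universe = set(universe)
    for cls, markers in marker_lists.items():
        if not set(markers) <= universe:
            raise ConfigurationError(
                f"marker list {cls!r} is not a subset of the universe"
            )
    m_total = len(universe)
    n_classes = len(marker_lists)

    rows = []
    labels: dict[tuple, str | None] = {}
    for (module, tissue), sub in modules.groupby(["MODULE", "TISSUE"]):
        module_genes = set(sub["GENE"]) & universe
        sig = []
        for cls, markers in marker_lists.items():
            k = len(module_genes & set(markers))
            # P(X >= k) for X ~ Hypergeom(M=universe, n=markers, N=module)
            p = stats.hypergeom.sf(k - 1, m_total, len(markers), len(module_genes))
            p_bonf = min(1.0, p * n_classes)
            rows.append((module, tissue, cls, p, p_bonf))
            if p_bonf < alpha:
                sig.append(cls)
        labels[(module, tissue)] = sig[0] if len(sig) == 1 else None

    pvalues = pd.DataFrame(
        rows, columns=["MODULE", "TISSUE", "CLASS", "P", "P_BONF"]
    )
    celltype_genes: dict[str, set] = {}
    passing = modules[
        (modules["KME"] >= MODULE_KME_MIN)
        & (modules["PRESERVATION_Z"] > MODULE_PRESERVATION_MIN)
    ]
    for (module, tissue), sub in passing.groupby(["MODULE", "TISSUE"]):
        label = labels.get((module, tissue))
        if label is None:
            continue
        celltype_genes.setdefault(label, set()).update(sub["GENE"])
    return ModuleLabeling(
        labels=labels, pvalues=pvalues, celltype_genes=celltype_genes
    )
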