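"""Readers and writers for the on-disk dialects.

Variants, summary statistics, annotations and LD scores use the tab-separated
dialects common in the heritability-partitioning toolchain:

* variants: ``CHR  BP  SNP  A1  A2  MAF`` (1-based positions)
* sumstats: ``SNP  A1  A2  Z  N``
* annot:    ``CHR  BP  SNP  CM`` followed by one binary column per category
* ldscore:  ``SNP`` followed by one ``<category>L2`` column per category
* eQTL:     ``SNP  GENE  SLOPE  P`` per tissue
* expression: gene x group matrix, first column ``GENE``
* gene sets: GMT (set name, description, then gene ids)

Every writer also emits a sidecar provenance record ``<path>.provenance.json``
carrying the seed/parameters supplied by the caller, so any file can be traced
back to the run that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotationMatrix,
    GeneTable,
    LdPanel,
    LdScoreTable,
    SumStats,
    VariantTable,
)
from .exceptions import DataError

_FLOAT_FMT = "%.10g"


def _write_provenance(path: Path, provenance: dict | None) -> None:
    if provenance is None:
        return
    side = Path(str(path) + ".provenance.json")
    side.write_text(json.dumps(provenance, indent=2, sort_keys=True, default=str))


# ---------------------------------------------------------------- variants


def write_variants(variants: VariantTable, path, provenance: dict | None = None):
    out = pd.DataFrame(
        {
            "CHR": variants.df["chrom"],
            "BP": variants.df["pos"],
            "SNP": variants.df["snp"],
            "A1": variants.df["a1"],
            "A2": variants.df["a2"],
            "MAF": variants.df["maf"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    _write_provenance(Path(path), provenance)


def read_variants(path) -> VariantTable:
    raw = pd.read_csv(path, sep="\t")
    return VariantTable(
        pd.DataFrame(
            {
                "snp": raw["SNP"],
                "chrom": raw["CHR"],
                "pos": raw["BP"],
                "a1": raw["A1"],
                "a2": raw["A2"],
                "maf": raw["MAF"],
            }
        )
    )


# ---------------------------------------------------------------- sumstats


def write_sumstats(
    sumstats: SumStats,
    variants: VariantTable,
    path,
    provenance: dict | None = None,
):
    """Write Z-score sumstats; Z is the positive root of chi2 (sign-free)."""
    alleles = variants.df.set_index("snp").loc[sumstats.snp, ["a1", "a2"]]
    out = pd.DataFrame(
        {
            "SNP": sumstats.snp.to_numpy(),
            "A1": alleles["a1"].to_numpy(),
            "A2": alleles["a2"].to_numpy(),
            "Z": np.sqrt(sumstats.chi2),
            "N": sumstats.n_gwas,
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    _write_provenance(Path(path), provenance)


def read_sumstats(path, trait: str | None = None) -> SumStats:
    raw = pd.read_csv(path, sep="\t")
    return SumStats.from_z(
        snp=raw["SNP"],
        z=raw["Z"],
        n_gwas=raw["N"].to_numpy(float),
        trait=trait or Path(path).stem,
    )


# ---------------------------------------------------------------- annot


def write_annot(annot: AnnotationMatrix, path, provenance: dict | None = None):
    v = annot.variants.df
    out = pd.DataFrame(
        {"CHR": v["chrom"], "BP": v["pos"], "SNP": v["snp"], "CM": 0.0}
    )
    for cat in annot.categories:
        out[cat] = annot.membership[cat].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    _write_provenance(Path(path), provenance)


def read_annot(path, variants: VariantTable) -> AnnotationMatrix:
    raw = pd.read_csv(path, sep="\t")
    if not np.array_equal(raw["SNP"].to_numpy(), variants.snp.to_numpy()):
        raise DataError("annot file SNP order does not match variant table")
    cats = [c for c in raw.columns if c not in ("CHR", "BP", "SNP", "CM")]
    return AnnotationMatrix(variants, raw[cats])


# ---------------------------------------------------------------- ldscore


def write_ldscores(table: LdScoreTable, path, provenance: dict | None = None):
    out = pd.DataFrame({"SNP": table.snp})
    for cat in table.categories:
        out[f"{cat}L2"] = table.scores[cat].to_numpy()
    out["baseL2_total"] = table.total
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    _write_provenance(Path(path), provenance)


def read_ldscores(path) -> LdScoreTable:
    raw = pd.read_csv(path, sep="\t")
    cats = [
        c[:-2] for c in raw.columns if c.endswith("L2") and c != "baseL2_total"
    ]
    scores = pd.DataFrame({c: raw[f"{c}L2"].to_numpy(float) for c in cats})
    return LdScoreTable(
        snp=raw["SNP"], scores=scores, total=raw["baseL2_total"].to_numpy(float)
    )


# ---------------------------------------------------------------- panel


def write_panel(panel: LdPanel, prefix, provenance: dict | None = None):
    """Write a panel as <prefix>.variants.tsv / .genotypes.tsv / .blocks.tsv."""
    prefix = Path(prefix)
    write_variants(panel.variants, f"{prefix}.variants.tsv", provenance)
    pd.DataFrame(panel.genotypes).to_csv(
        f"{prefix}.genotypes.tsv", sep="\t", index=False, header=False
    )
    pd.DataFrame({"BLOCK": panel.block_index}).to_csv(
        f"{prefix}.blocks.tsv", sep="\t", index=False
    )


def read_panel(prefix) -> LdPanel:
    prefix = Path(prefix)
    variants = read_variants(f"{prefix}.variants.tsv")
    genotypes = pd.read_csv(
        f"{prefix}.genotypes.tsv", sep="\t", header=None
    ).to_numpy(np.int8)
    blocks = pd.read_csv(f"{prefix}.blocks.tsv", sep="\t")["BLOCK"].to_numpy()
    return LdPanel(genotypes, variants, blocks)


# ---------------------------------------------------------------- expression


def write_expression(expr: pd.DataFrame, path, provenance: dict | None = None):
    out = expr.copy()
    out.insert(0, "GENE", expr.index)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    _write_provenance(Path(path), provenance)


def read_expression(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    return raw.set_index("GENE").rename_axis(index=None)


def write_gene_meta(meta: pd.DataFrame, path, provenance: dict | None = None):
    out = meta.copy()
    out.insert(0, "GENE", meta.index)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    _write_provenance(Path(path), provenance)


def read_gene_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("GENE").rename_axis(index=None)


# ---------------------------------------------------------------- genes


def write_genes(genes: GeneTable, path, provenance: dict | None = None):
    out = pd.DataFrame(
        {
            "GENE": genes.df["gene"],
            "CHR": genes.df["chrom"],
            "TX_START": genes.df["tx_start"],
            "TX_END": genes.df["tx_end"],
            "STRAND": genes.df["strand"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
    _write_provenance(Path(path), provenance)


def read_genes(path) -> GeneTable:
    raw = pd.read_csv(path, sep="\t")
    return GeneTable(
        pd.DataFrame(
            {
                "gene": raw["GENE"],
                "chrom": raw["CHR"],
                "tx_start": raw["TX_START"],
                "tx_end": raw["TX_END"],
                "strand": raw["STRAND"],
            }
        )
    )


# ---------------------------------------------------------------- eQTL


def write_eqtl_table(table: pd.DataFrame, path, provenance: dict | None = None):
    table[["SNP", "GENE", "SLOPE", "P"]].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )
    _write_provenance(Path(path), provenance)


def read_eqtl_table(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    needed = {"SNP", "GENE", "SLOPE", "P"}
    if not needed.issubset(raw.columns):
        raise DataError(f"eQTL table must have columns {sorted(needed)}")
    return raw


# ---------------------------------------------------------------- gene sets


def read_gmt(path) -> dict[str, set]:
    """Read a GMT file into {set name: set of gene ids}."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict, path, provenance: dict | None = None):
    lines = [
        "\t".join([name, "na"] + sorted(genes)) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
    _write_provenance(Path(path), provenance)


def read_gene_list(path) -> list[str]:
    """One gene id per line."""
    return [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]


# ---------------------------------------------------------------- misc tables


def read_ortholog_map(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    if raw.shape[1] < 2:
        raise DataError("ortholog map needs two columns (source, target)")
    raw = raw.iloc[:, :2]
    raw.columns = ["source", "target"]
    return raw


def read_module_table(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    needed = {"MODULE", "TISSUE", "GENE", "KME", "PRESERVATION_Z"}
    if not needed.issubset(raw.columns):
        raise DataError(f"module table must have columns {sorted(needed)}")
    return raw


def write_bed(intervals: pd.DataFrame, path):
    """Write intervals as BED (0-based half-open).

    ``intervals`` must have columns chrom, start, end in 1-based inclusive
    coordinates; the conversion to BED happens here, at the I/O boundary.
    """
    out = pd.DataFrame(
        {
            "chrom": intervals["chrom"].map(lambda c: f"chr{c}"),
            "start": intervals["start"].astype(int) - 1,
            "end": intervals["end"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)
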