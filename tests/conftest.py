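"""Shared fixtures: small synthetic panels, gene tables and the session-scope
simulation study reused by the regression calibration tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from strath2 import (
    AnnotationMatrix,
    GeneTable,
    VariantTable,
    compute_ld_scores,
    simulate_expression,
    simulate_ld_panel,
)

settings.register_profile("fixed", derandomize=True, max_examples=50)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def small_panel():
    """200-SNP panel (4 blocks x 50, rho=0.4) for oracle comparisons."""
    return simulate_ld_panel(120, 4, 50, rho=0.4, seed=42)


@pytest.fixture(scope="session")
def study_panel():
    """The 5,000-SNP study panel: 50 LD blocks x 100 SNPs, rho=0.5, n=500."""
    return simulate_ld_panel(500, 50, 100, rho=0.5, seed=11)


@pytest.fixture(scope="session")
def study_annot(study_panel):
    """2-category baseline (all SNPs, even blocks) plus a 10% test category."""
    m = study_panel.n_variants
    rng = np.random.default_rng(7)
    return AnnotationMatrix.from_columns(
        study_panel.variants,
        {
            "all_snps": np.ones(m, dtype=int),
            "even_blocks": (study_panel.block_index % 2 == 0).astype(int),
            "enriched": (rng.random(m) < 0.1).astype(int),
        },
    )


@pytest.fixture(scope="session")
def study_ldscores(study_panel, study_annot):
    return compute_ld_scores(study_panel, study_annot)


@pytest.fixture(scope="session")
def marker_fixture():
    """2,000 genes x 4 cell types with 50 planted markers per type."""
    return simulate_expression(
        2000,
        ["neuron", "microglia", "astrocyte", "oligodendrocyte"],
        markers_per_group=50,
        fold=5.0,
        noise_sd=0.3,
        seed=3,
    )


@pytest.fixture()
def toy_variants():
    """Hand-laid variants bracketing a 100 kb window boundary plus MHC SNPs."""
    rows = [
        ("rs_a", 1, 905_000),  # 100 kb window: inside, 95 kb upstream
        ("rs_b", 1, 899_999),  # 1 bp outside the upstream window edge
        ("rs_c", 1, 1_005_000),  # inside the gene body
        ("rs_d", 1, 1_110_000),  # exactly at the downstream edge (inside)
        ("rs_e", 1, 1_110_001),  # 1 bp beyond
        ("rs_f", 2, 1_005_000),  # wrong chromosome
        ("rs_mhc", 6, 26_000_000),  # inside the MHC
        ("rs_chr6", 6, 40_000_000),  # chr6 but outside the MHC
    ]
    return VariantTable(
        pd.DataFrame(
            {
                "snp": [r[0] for r in rows],
                "chrom": [r[1] for r in rows],
                "pos": [r[2] for r in rows],
                "a1": "A",
                "a2": "G",
                "maf": 0.3,
            }
        ).sort_values(["chrom", "pos"])
    )


@pytest.fixture()
def toy_genes():
    return GeneTable(
        pd.DataFrame(
            {
                "gene": ["GENE1", "GENE2", "GENE_MHC"],
                "chrom": [1, 1, 6],
                "tx_start": [1_000_000, 100_000, 26_000_000],
                "tx_end": [1_010_000, 120_000, 26_010_000],
                "strand": ["+", "+", "+"],
            }
        )
    )
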