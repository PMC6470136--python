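"""Annotation builders: specificity ranking, window expansion, eQTL
assignment, module labeling, ortholog mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.special import comb

from strath2 import (
    GeneTable,
    assign_eqtls_by_effect,
    build_geneset_annotation,
    celltype_enrichment_scores,
    genes_to_snp_annotation,
    label_module_celltype,
    map_orthologs,
    tissue_specificity_tstat,
    top_fraction_genes,
)
from strath2.exceptions import (
    ConfigurationError,
    DataError,
    EmptyCategoryError,
)


class TestTissueSpecificity:
    @pytest.fixture()
    def expr_setup(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(12)]
        tissues = pd.Series(
            ["cortex"] * 4 + ["liver"] * 4 + ["blood"] * 4, index=samples
        )
        expr = pd.DataFrame(
            rng.lognormal(1, 0.5, size=(30, 12)),
            index=[f"g{i}" for i in range(30)],
            columns=samples,
        )
        cats = {"cortex": "brain", "liver": "organ", "blood": "organ"}
        return expr, tissues, cats

    def test_flat_gene_scores_zero_everywhere(self, expr_setup):
        expr, tissues, cats = expr_setup
        expr.loc["g0"] = 7.0
        out = tissue_specificity_tstat(expr, tissues, cats)
        assert (out.loc["g0"].abs() < 1e-12).all()

    def test_zero_variance_flagged_not_infinite(self, expr_setup):
        expr, tissues, cats = expr_setup
        expr.loc["g1"] = 0.0
        expr.loc["g1", ["s0", "s1", "s2", "s3"]] = 10.0
        out = tissue_specificity_tstat(expr, tissues, cats)
        assert np.isnan(out.loc["g1", "cortex"])

    def test_matches_welch_oracle(self, expr_setup):
        """Scores equal an independently computed Welch two-sample t."""
        expr, tissues, cats = expr_setup
        out = tissue_specificity_tstat(expr, tissues, cats)
        own = expr.columns[tissues.loc[expr.columns] == "cortex"]
        other = expr.columns[
            [cats[t] != "brain" for t in tissues.loc[expr.columns]]
        ]
        for g in ["g2", "g7", "g15"]:
            ref = stats.ttest_ind(
                expr.loc[g, own], expr.loc[g, other], equal_var=False
            ).statistic
            assert out.loc[g, "cortex"] == pytest.approx(ref, abs=1e-10)

    def test_exclusion_covering_everything_rejected(self, expr_setup):
        expr, tissues, _ = expr_setup
        cats = {"cortex": "x", "liver": "x", "blood": "x"}
        with pytest.raises(ConfigurationError):
            tissue_specificity_tstat(expr, tissues, cats)


class TestTopFraction:
    def test_ceil_rule_and_identity(self):
        scores = pd.Series(np.arange(20, dtype=float), index=[f"g{i:02d}" for i in range(20)])
        assert len(top_fraction_genes(scores, 0.1)) == 2
        assert set(top_fraction_genes(scores, 0.1)) == {"g19", "g18"}
        assert len(top_fraction_genes(scores, 1.0)) == 20

    def test_all_ties_selects_lexicographically_smallest(self):
        scores = pd.Series(1.0, index=[f"g{i}" for i in range(10)])
        assert top_fraction_genes(scores, 0.1) == ["g0"]

    def test_all_missing_rejected(self):
        with pytest.raises(DataError):
            top_fraction_genes(pd.Series([np.nan, np.nan]), 0.5)

    @given(
        n=st.integers(2, 60),
        frac=st.floats(0.05, 1.0),
        seed=st.integers(0, 100),
    )
    def test_count_follows_ceil_and_reapplication_is_idempotent(self, n, frac, seed):
        rng = np.random.default_rng(seed)
        scores = pd.Series(rng.normal(size=n), index=[f"g{i:03d}" for i in range(n)])
        top = top_fraction_genes(scores, frac)
        assert len(top) == int(np.ceil(frac * n))
        again = top_fraction_genes(scores.loc[top], 1.0)
        assert sorted(again) == sorted(top)


class TestWindowExpansion:
    def test_window_boundaries_exact(self, toy_genes, toy_variants):
        gene1 = toy_genes.subset_ids(["GENE1"])
        col = genes_to_snp_annotation(gene1, toy_variants, window=100_000)
        got = dict(zip(toy_variants.snp, col))
        assert got["rs_a"] == 1  # 95 kb upstream
        assert got["rs_b"] == 0  # 1 bp beyond the upstream edge
        assert got["rs_c"] == 1  # inside gene body
        assert got["rs_d"] == 1  # exactly 100 kb downstream
        assert got["rs_e"] == 0  # 1 bp beyond
        assert got["rs_f"] == 0  # other chromosome

    def test_overlapping_windows_count_once(self, toy_variants):
        genes = GeneTable(
            pd.DataFrame(
                {
                    "gene": ["X", "Y"],
                    "chrom": [1, 1],
                    "tx_start": [1_000_000, 1_001_000],
                    "tx_end": [1_010_000, 1_012_000],
                    "strand": ["+", "-"],
                }
            )
        )
        col = genes_to_snp_annotation(genes, toy_variants, window=100_000)
        assert set(np.unique(col)) <= {0, 1}
        got = dict(zip(toy_variants.snp, col))
        assert got["rs_c"] == 1

    def test_geneset_annotation_reports_unresolved_and_rejects_empty(
        self, toy_genes, toy_variants
    ):
        col, unresolved = build_geneset_annotation(
            {"GENE1", "NOT_A_GENE"}, toy_genes, toy_variants
        )
        assert unresolved == ["NOT_A_GENE"]
        assert col.sum() > 0
        with pytest.raises(EmptyCategoryError):
            build_geneset_annotation(set(), toy_genes, toy_variants)
        with pytest.raises(EmptyCategoryError):
            build_geneset_annotation({"NOPE"}, toy_genes, toy_variants)

    def test_pli_threshold_boundary(self, toy_genes, toy_variants):
        """Gene-level constraint filter: pLI >= 0.9 keeps 0.90, drops 0.8999."""
        pli = pd.Series({"GENE1": 0.90, "GENE2": 0.8999})
        lof_intolerant = set(pli.index[pli >= 0.9])
        assert lof_intolerant == {"GENE1"}

    def test_mhc_mask(self, toy_variants):
        mask = toy_variants.mhc_mask()
        got = dict(zip(toy_variants.snp, mask))
        assert not got["rs_mhc"]
        assert got["rs_chr6"]
        assert got["rs_a"]


class TestCelltypeEnrichment:
    def test_fold_enrichment_examples(self):
        expr = pd.DataFrame(
            [[4.0, 1.0, 1.0], [0.0, 1.0, 1.0], [5.0, 0.0, 0.0]],
            index=["g1", "g2", "g3"],
            columns=["a", "b", "c"],
        )
        enr = celltype_enrichment_scores(expr, detection_rule="gt_0")
        assert enr.loc["g1", "a"] == pytest.approx(4.0, rel=1e-6)
        assert enr.loc["g2", "a"] == 0.0
        # exclusive expression outranks any finite competitor, matching a
        # brute-force ranking that treats a zero denominator as +inf
        brute = {}
        for g in expr.index:
            x = expr.loc[g]
            denom = (x.sum() - x["a"]) / 2
            brute[g] = np.inf if denom == 0 and x["a"] > 0 else (
                0.0 if x["a"] == 0 else x["a"] / denom
            )
        brute_order = sorted(brute, key=lambda g: (-brute[g], g))
        enr_order = list(enr["a"].sort_values(ascending=False).index)
        assert enr_order == brute_order

    def test_detection_rules(self):
        expr = pd.DataFrame(
            [[0.5, 0.2], [0.0, 0.0], [2.0, 0.1]],
            index=["low", "zero", "high"],
            columns=["a", "b"],
        )
        assert list(celltype_enrichment_scores(expr, "fpkm_ge_1").index) == ["high"]
        assert list(celltype_enrichment_scores(expr, "gt_0").index) == ["low", "high"]

    def test_single_cell_type_rejected(self):
        with pytest.raises(ConfigurationError):
            celltype_enrichment_scores(pd.DataFrame({"only": [1.0, 2.0]}))


class TestOrthologs:
    def test_one_to_one_maps_cleanly(self):
        mapping = pd.DataFrame(
            {"source": [f"m{i}" for i in range(5)],
             "target": [f"H{i}" for i in range(5)]}
        )
        mapped, report = map_orthologs([f"m{i}" for i in range(5)], mapping)
        assert mapped == [f"H{i}" for i in range(5)]
        assert report.empty

    def test_one_to_many_dropped_with_reason(self):
        mapping = pd.DataFrame(
            {"source": ["m1", "m1", "m2"], "target": ["H1a", "H1b", "H2"]}
        )
        mapped, report = map_orthologs(["m1", "m2"], mapping)
        assert mapped == ["H2"]
        assert report.set_index("gene").loc["m1", "reason"] == "one-to-many"

    def test_irrelevant_mapping_rows_ignored(self):
        mapping = pd.DataFrame(
            {"source": ["m1", "m_extra"], "target": ["H1", "H_extra"]}
        )
        mapped, report = map_orthologs(["m1"], mapping)
        assert mapped == ["H1"]
        assert report.empty

    def test_empty_mapping_rejected(self):
        with pytest.raises(ConfigurationError):
            map_orthologs(["m1"], pd.DataFrame(columns=["source", "target"]))


class TestEqtlAssignment:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["SNP", "GENE", "TISSUE", "SLOPE", "P", "Q"]
        )

    def test_brain_collapse_keeps_max_abs_slope(self):
        """A SNP replicated across brain regions collapses to the maximum
        absolute slope, then beats an absent blood record."""
        rec = self._records(
            [
                ("rs1", "g1", "cortex", 0.3, 1e-8, 1e-6),
                ("rs1", "g1", "putamen", -0.8, 1e-9, 1e-7),
            ]
        )
        out = assign_eqtls_by_effect(
            rec, grouping={"cortex": "brain", "putamen": "brain", "blood": "blood"}
        )
        assert out == {"brain": {"rs1"}}

    def test_blood_wins_on_larger_effect(self):
        rec = self._records(
            [
                ("rs1", "g1", "cortex", 0.4, 1e-8, 1e-6),
                ("rs1", "g2", "blood", 0.6, 1e-8, 1e-6),
            ]
        )
        out = assign_eqtls_by_effect(
            rec, grouping={"cortex": "brain", "blood": "blood"}
        )
        assert out["blood"] == {"rs1"}
        assert out.get("brain", set()) == set()

    def test_singleton_tissue_keeps_snp(self):
        rec = self._records([("rs9", "g1", "cerebellum", -0.01, 1e-8, 1e-6)])
        out = assign_eqtls_by_effect(rec)
        assert out == {"cerebellum": {"rs9"}}

    def test_tie_goes_to_lexicographically_first_group(self, caplog):
        rec = self._records(
            [
                ("rs1", "g1", "zeta", 0.5, 1e-8, 1e-6),
                ("rs1", "g1", "alpha", -0.5, 1e-8, 1e-6),
            ]
        )
        with caplog.at_level("WARNING"):
            out = assign_eqtls_by_effect(rec)
        assert out["alpha"] == {"rs1"}
        assert any("ties" in m for m in caplog.messages)

    def test_outputs_partition_the_collapsed_universe(self):
        rng = np.random.default_rng(1)
        rows = []
        tissues = ["cortex", "putamen", "blood"]
        for i in range(60):
            for t in tissues:
                if rng.random() < 0.6:
                    rows.append(
                        (f"rs{i}", f"g{rng.integers(5)}", t,
                         rng.normal(0, 0.5), 1e-8, 1e-6)
                    )
        rec = self._records(rows)
        grouping = {"cortex": "brain", "putamen": "brain", "blood": "blood"}
        out = assign_eqtls_by_effect(rec, grouping)
        all_assigned = [s for v in out.values() for s in v]
        assert len(all_assigned) == len(set(all_assigned))  # disjoint
        assert set(all_assigned) == set(rec["SNP"])  # exhaustive


class TestModuleLabeling:
    def _modules(self, rows):
        return pd.DataFrame(
            rows, columns=["MODULE", "TISSUE", "GENE", "KME", "PRESERVATION_Z"]
        )

    def test_hypergeometric_matches_enumeration(self):
        """Upper-tail p equals the brute-force sum of point masses."""
        universe = {f"g{i}" for i in range(1000)}
        markers = {f"g{i}" for i in range(20)}
        module_genes = [f"g{i}" for i in range(5)] + [f"g{i}" for i in range(500, 505)]
        rows = [("M1", "ctx", g, 0.9, 5.0) for g in module_genes]
        lab = label_module_celltype(
            self._modules(rows), {"neuron": markers}, universe
        )
        p = lab.pvalues.set_index("CLASS").loc["neuron", "P"]
        n_mod, n_mark, m_tot, k = 10, 20, 1000, 5
        brute = sum(
            comb(n_mark, i, exact=True)
            * comb(m_tot - n_mark, n_mod - i, exact=True)
            for i in range(k, min(n_mod, n_mark) + 1)
        ) / comb(m_tot, n_mod, exact=True)
        assert p == pytest.approx(brute, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(100)}
        rows = [("M1", "ctx", f"g{i}", 0.9, 5.0) for i in range(50, 60)]
        lab = label_module_celltype(
            self._modules(rows), {"neuron": {f"g{i}" for i in range(10)}}, universe
        )
        assert lab.pvalues["P"].iloc[0] == pytest.approx(1.0)

    def test_two_significant_classes_leave_module_unlabeled(self):
        universe = {f"g{i}" for i in range(1000)}
        neuron = {f"g{i}" for i in range(10)}
        glia = {f"g{i}" for i in range(10, 20)}
        rows = [("M1", "ctx", f"g{i}", 0.9, 5.0) for i in range(20)]
        lab = label_module_celltype(
            self._modules(rows), {"neuron": neuron, "microglia": glia}, universe
        )
        assert lab.labels[("M1", "ctx")] is None
        assert lab.celltype_genes == {}

    def test_membership_and_preservation_filters(self):
        universe = {f"g{i}" for i in range(500)}
        markers = {f"g{i}" for i in range(15)}
        rows = (
            [("M1", "ctx", f"g{i}", 0.9, 5.0) for i in range(10)]
            + [("M1", "ctx", "g100", 0.4, 5.0)]  # kME below 0.5
            + [("M2", "ctx", "g200", 0.9, 1.5)]  # preservation below 2
        )
        lab = label_module_celltype(
            self._modules(rows), {"neuron": markers}, universe
        )
        assert lab.labels[("M1", "ctx")] == "neuron"
        assert "g100" not in lab.celltype_genes["neuron"]
        assert "g200" not in lab.celltype_genes.get("neuron", set())

    def test_marker_list_outside_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            label_module_celltype(
                self._modules([("M1", "ctx", "g1", 0.9, 5.0)]),
                {"neuron": {"not_in_universe"}},
                {"g1"},
            )


def _window_property_tables():
    from strath2 import VariantTable

    rng = np.random.default_rng(2024)
    pos = np.sort(rng.integers(1, 2_000_000, size=80))
    pos = np.unique(pos)
    variants = VariantTable(
        pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(len(pos))],
                "chrom": 1,
                "pos": pos,
                "a1": "A",
                "a2": "G",
                "maf": 0.2,
            }
        )
    )
    genes = GeneTable(
        pd.DataFrame(
            {
                "gene": ["A", "B"],
                "chrom": [1, 1],
                "tx_start": [500_000, 1_200_000],
                "tx_end": [520_000, 1_250_000],
                "strand": ["+", "-"],
            }
        )
    )
    return genes, variants


@given(w1=st.integers(0, 150_000), w2=st.integers(0, 150_000))
def test_annotation_columns_are_binary_and_union_monotone(w1, w2):
    """Bigger windows never lose SNPs; columns stay binary."""
    genes, variants = _window_property_tables()
    lo, hi = sorted([w1, w2])
    col_lo = genes_to_snp_annotation(genes, variants, window=lo)
    col_hi = genes_to_snp_annotation(genes, variants, window=hi)
    assert set(np.unique(col_lo)) <= {0, 1}
    assert (col_hi >= col_lo).all()
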