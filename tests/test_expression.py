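"""BH adjustment, concordance filtering, and rank-test validations."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from regland.expression import (
    DERecord,
    ExpressionMatrix,
    bh_adjust,
    concordant_genes,
    cross_population_validation,
    export_gene_lists,
    near_vs_global_expression,
    read_de_table,
)
from regland.specificity import SpecificityLabel

from oracles import brute_bh, rank_sum_exact_p


class TestBHAdjust:
    def test_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_degenerate_cases(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)
        assert bh_adjust([]).size == 0

    @pytest.mark.parametrize("bad", [[-0.1], [1.1], [float("nan")]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)

    def test_matches_brute_force_and_statsmodels(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            got = bh_adjust(p)
            assert got == pytest.approx(brute_bh(list(p)))
            assert got == pytest.approx(
                multipletests(p, method="fdr_bh")[1], abs=1e-12
            )

    def test_output_dominates_input_and_stays_in_unit_interval(self, rng):
        p = rng.uniform(0, 1, size=100)
        q = bh_adjust(p)
        assert np.all(q >= p) and np.all(q <= 1.0)


def de(gene, log2fc, padj, pvalue=None):
    return DERecord(gene, log2fc, pvalue if pvalue is not None else min(padj, 1.0), padj)


def label(rid, label_name, comparison=("NSC", "IPS")):
    side = 0 if label_name in ("specific_A",) else 1
    return SpecificityLabel(rid, comparison, label_name, side=side)


class TestConcordantGenes:
    links = {"r1": ["up_strong", "up_weak", "up_notsig", "absent"],
             "r2": ["down_strong"]}
    de_table = {
        "up_strong": de("up_strong", 2.0, 0.01),
        "up_weak": de("up_weak", 1.2, 0.01),
        "up_notsig": de("up_notsig", 2.0, 0.2),
        "down_strong": de("down_strong", -2.0, 0.001),
    }

    def run(self, region_class="enhancer", threshold=None):
        labels = [label("r1", "specific_A"), label("r2", "specific_B")]
        return concordant_genes(labels, self.links, self.de_table, region_class,
                                threshold)

    def test_enhancer_threshold_and_padj_gate(self):
        sets = self.run()
        assert sets["NSC"].gene_ids == ["up_strong"]   # 1.2 < 1.5; padj 0.2 dropped
        assert sets["NSC"].n_missing == 1              # "absent" not in DE table
        assert sets["IPS"].gene_ids == ["down_strong"]

    def test_se_threshold_admits_weaker_fold_change(self):
        sets = self.run(region_class="superenhancer")
        assert sets["NSC"].gene_ids == ["up_strong", "up_weak"]

    def test_direction_tied_to_specific_side(self):
        # A down-regulated gene never passes for an A-specific region.
        labels = [label("r2", "specific_A")]
        sets = concordant_genes(labels, self.links, self.de_table, "enhancer")
        assert sets["NSC"].gene_ids == []

    def test_tightening_thresholds_shrinks_output(self):
        sizes = []
        for thr in (1.0, 1.5, 2.0, 2.5):
            sets = self.run(threshold=thr)
            sizes.append(sum(len(s.genes) for s in sets.values()))
        assert sizes == sorted(sizes, reverse=True)

    def test_duplicate_links_counted_once(self):
        links = {"r1": ["up_strong"], "r3": ["up_strong"]}
        labels = [label("r1", "specific_A"), label("r3", "specific_A")]
        sets = concordant_genes(labels, links, self.de_table, "enhancer")
        assert sets["NSC"].gene_ids == ["up_strong"]


def expr_matrix(data, conditions=("A", "B")):
    n_rep = data.shape[1] // len(conditions)
    cols, cmap = [], {}
    for c in conditions:
        for r in range(n_rep):
            name = f"{c}:rep{r + 1}"
            cols.append(name)
            cmap[name] = c
    genes = [f"g{i:03d}" for i in range(data.shape[0])]
    return ExpressionMatrix(pd.DataFrame(data, index=genes, columns=cols), cmap)


class TestNearVsGlobal:
    def test_exact_small_sample_matches_enumeration(self):
        # 3 region genes vs 4 background genes: 35 possible rank assignments.
        values = np.array([9.0, 7.5, 8.2, 1.0, 2.0, 3.0, 4.0])
        data = np.repeat(values[:, None], 2, axis=1)
        expr = expr_matrix(data, conditions=("A",))
        res = near_vs_global_expression(["g000", "g001", "g002"], expr, "A")
        expected = rank_sum_exact_p([9.0, 7.5, 8.2], [1.0, 2.0, 3.0, 4.0])
        assert res.pvalue == pytest.approx(expected)
        assert expected == pytest.approx(1 / 35)
        assert "exact" in res.method

    def test_exact_and_asymptotic_agree_at_boundary_size(self, rng):
        # At n = 8 per group the two branches should differ by < 0.01.
        from scipy.stats import mannwhitneyu

        for _ in range(20):
            x = rng.normal(0.5, 1, 8)
            y = rng.normal(0.0, 1, 8)
            exact = mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
            approx = mannwhitneyu(x, y, alternative="greater",
                                  method="asymptotic", use_continuity=True).pvalue
            assert abs(exact - approx) < 0.01

    def test_shifted_region_genes_detected(self, rng):
        data = rng.normal(5, 1.5, size=(200, 4))
        data[:20] += 4.0
        expr = expr_matrix(data, conditions=("A",))
        res = near_vs_global_expression([f"g{i:03d}" for i in range(20)], expr, "A")
        assert res.pvalue < 1e-6
        assert res.median_region > res.median_background

    def test_empty_or_tiny_groups_rejected(self, rng):
        expr = expr_matrix(rng.normal(size=(5, 2)), conditions=("A",))
        with pytest.raises(ValueError, match="empty"):
            near_vs_global_expression([], expr, "A")
        with pytest.raises(ValueError, match=">=2"):
            near_vs_global_expression(["g000"], expr, "A")


class TestCrossPopulation:
    def test_identical_conditions_are_null(self, rng):
        half = rng.normal(5, 1, size=(20, 3))
        data = np.hstack([half, half])  # A and B identical
        expr = expr_matrix(data)
        res = cross_population_validation([f"g{i:03d}" for i in range(20)],
                                          expr, "A", "B")
        assert res.pvalue == 1.0
        assert res.median_region == 0.0

    def test_planted_effect_detected(self, rng):
        data = rng.normal(5, 0.5, size=(30, 6))
        data[:15, :3] += 2.0  # up in A for the first 15 genes
        expr = expr_matrix(data)
        res = cross_population_validation([f"g{i:03d}" for i in range(15)],
                                          expr, "A", "B")
        assert res.pvalue < 1e-3
        assert res.median_region > 1.0

    def test_single_gene_rejected(self, rng):
        expr = expr_matrix(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match=">=2"):
            cross_population_validation(["g000"], expr, "A", "B")


class TestExportGeneLists:
    def make_set(self, genes):
        from regland.expression import ConcordantGeneSet

        return ConcordantGeneSet(("NSC", "IPS"), "enhancer", 400, "NSC", genes)

    def test_empty_set_writes_header_only(self, tmp_path):
        (tsv, txt) = export_gene_lists([self.make_set([])], tmp_path)
        assert tsv.read_text() == "gene_id\tlog2fc\tpadj\n"
        assert txt.read_text() == ""

    def test_deterministic_ranked_order(self, tmp_path):
        genes = [("b", 2.0, 0.01), ("a", 2.0, 0.01), ("c", -3.0, 0.001)]
        ranked = sorted(genes, key=lambda t: (-abs(t[1]), t[0]))
        first = export_gene_lists([self.make_set(ranked)], tmp_path / "x")
        second = export_gene_lists([self.make_set(ranked)], tmp_path / "y")
        assert first[0].read_text() == second[0].read_text()
        assert first[1].read_text().splitlines() == ["c", "a", "b"]


class TestDETableIO:
    def test_padj_recomputed_when_absent(self, tmp_path):
        f = tmp_path / "de.tsv"
        f.write_text(
            "gene_id\tlog2fc\tpvalue\n"
            "g1\t1.0\t0.01\ng2\t-0.5\t0.02\ng3\t0.1\t0.03\ng4\t0.0\t0.04\n"
        )
        recs = read_de_table(f)
        assert [r.padj for r in recs] == pytest.approx([0.04] * 4)

    def test_padj_invariant_enforced(self):
        with pytest.raises(ValueError):
            DERecord("g", 0.0, 0.5, 1.5)
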