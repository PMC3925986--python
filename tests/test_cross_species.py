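import numpy as np
import pandas as pd
import pytest

import embryostage as es
from conftest import make_counts, make_sheet
from oracles import kendall_taub_oracle, pearson_oracle, spearman_oracle, upgma_oracle


def ortholog_table(pairs):
    return es.OrthologTable(
        pd.DataFrame(pairs, columns=["gene_a", "gene_b"])
    )


class TestMapOrthologs:
    def test_disjoint_sets_give_nothing(self):
        ot = ortholog_table([("a1", "b1")])
        assert es.map_orthologs({"x"}, {"y"}, ot) == []

    def test_full_coverage_returns_whole_table(self):
        ot = ortholog_table([("a1", "b1"), ("a2", "b2")])
        pairs = es.map_orthologs({"a1", "a2"}, {"b1", "b2"}, ot)
        assert sorted(pairs) == [("a1", "b1"), ("a2", "b2")]

    def test_random_subsets_equal_brute_force_join(self):
        rng = np.random.default_rng(3)
        ot = ortholog_table([(f"a{i}", f"b{i}") for i in range(200)])
        genes_a = {f"a{i}" for i in rng.choice(200, 80, replace=False)}
        genes_b = {f"b{i}" for i in rng.choice(200, 90, replace=False)}
        got = set(es.map_orthologs(genes_a, genes_b, ot))
        brute = {
            (f"a{i}", f"b{i}")
            for i in range(200)
            if f"a{i}" in genes_a and f"b{i}" in genes_b
        }
        assert got == brute


class TestOverlapStats:
    def test_two_set_arithmetic(self):
        a = {f"g{i}" for i in range(100)}
        b = {f"g{i}" for i in range(75, 125)}
        rep = es.overlap_stats({"A": a, "B": b})
        assert rep.intersections[("A", "B")] == 25
        assert rep.shared_pct["A"] == pytest.approx(25.0)
        assert rep.shared_pct["B"] == pytest.approx(50.0)
        assert rep.jaccard[("A", "B")] == pytest.approx(0.2)

    def test_identical_sets(self):
        s = {"x", "y"}
        rep = es.overlap_stats({"A": set(s), "B": set(s)})
        assert rep.shared_pct == {"A": 100.0, "B": 100.0}
        assert rep.jaccard[("A", "B")] == 1.0

    def test_empty_set_flagged_undefined_not_zero(self):
        rep = es.overlap_stats({"A": {"x"}, "B": set()})
        assert "B" in rep.undefined
        assert np.isnan(rep.shared_pct["B"])

    def test_three_way_inclusion_exclusion(self):
        rng = np.random.default_rng(7)
        pool = [f"g{i}" for i in range(300)]
        sets = {
            k: set(rng.choice(pool, rng.integers(50, 200), replace=False))
            for k in "ABC"
        }
        rep = es.overlap_stats(sets)
        a, b, c = sets["A"], sets["B"], sets["C"]
        union = len(a | b | c)
        incl_excl = (
            len(a) + len(b) + len(c)
            - rep.intersections[("A", "B")]
            - rep.intersections[("A", "C")]
            - rep.intersections[("B", "C")]
            + rep.intersections[("A", "B", "C")]
        )
        assert union == incl_excl


class TestSimilarity:
    def random_em(self, n_genes=500, n_samples=4, seed=0):
        rng = np.random.default_rng(seed)
        vals = pd.DataFrame(
            rng.lognormal(2, 1.5, size=(n_genes, n_samples)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
        sheet = make_sheet(list(vals.columns), ["oocyte"] * n_samples)
        return es.ExpressionMatrix(vals, sheet)

    def test_self_similarity_is_unity_for_all_coefficients(self):
        em = self.random_em()
        sims = es.similarity(em)
        for coef in ("pearson", "spearman", "kendall"):
            assert np.allclose(np.diag(sims[coef]), 1.0)
            assert np.allclose(sims[coef], sims[coef].T)

    def test_decreasing_monotone_transform_gives_spearman_minus_one(self):
        em = self.random_em(n_samples=1)
        vals = em.values.copy()
        vals["s_neg"] = 1.0 / (vals["s0"] + 1.0)  # strictly decreasing transform
        sheet = make_sheet(["s0", "s_neg"], ["oocyte", "oocyte"])
        em2 = es.ExpressionMatrix(vals, sheet)
        sims = es.similarity(em2, coefficients=("spearman", "kendall"))
        assert sims["spearman"].loc["s0", "s_neg"] == pytest.approx(-1.0)
        assert sims["kendall"].loc["s0", "s_neg"] == pytest.approx(-1.0)

    def test_matches_definition_level_oracles(self):
        em = self.random_em(n_genes=500, n_samples=3, seed=11)
        sims = es.similarity(em, log_base=10, pseudocount=1.0)
        logged = np.log10(em.values.to_numpy() + 1.0)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            x, y = list(logged[:, i]), list(logged[:, j])
            si, sj = f"s{i}", f"s{j}"
            assert sims["pearson"].loc[si, sj] == pytest.approx(
                pearson_oracle(x, y), abs=1e-10
            )
            assert sims["spearman"].loc[si, sj] == pytest.approx(
                spearman_oracle(x, y), abs=1e-10
            )
            assert sims["kendall"].loc[si, sj] == pytest.approx(
                kendall_taub_oracle(x, y), abs=1e-10
            )

    def test_constant_sample_reported_missing(self):
        em = self.random_em(n_samples=2)
        vals = em.values.copy()
        vals["s1"] = 5.0
        em2 = es.ExpressionMatrix(vals, em.samples)
        sims = es.similarity(em2, coefficients=("pearson",))
        assert np.isnan(sims["pearson"].loc["s0", "s1"])

    def test_gene_order_permutation_invariant(self):
        em = self.random_em(seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(em.values.index)
        em_p = es.ExpressionMatrix(em.values.loc[perm], em.samples)
        s1 = es.similarity(em, coefficients=("pearson",))["pearson"]
        s2 = es.similarity(em_p, coefficients=("pearson",))["pearson"]
        assert np.allclose(s1, s2)

    def test_cross_species_alignment_through_orthologs(self):
        em_a = self.random_em(n_genes=100, n_samples=2, seed=1)
        vals_b = em_a.values.copy()
        vals_b.index = [f"b_{g}" for g in em_a.values.index]
        vals_b.columns = ["t0", "t1"]
        em_b = es.ExpressionMatrix(
            vals_b, make_sheet(["t0", "t1"], ["oocyte", "oocyte"], species="mouse")
        )
        ot = ortholog_table([(g, f"b_{g}") for g in em_a.values.index])
        sims = es.similarity(em_a, em_b, ot, coefficients=("pearson",))
        # sample s0 and its renamed copy t0 correlate perfectly
        assert sims["pearson"].loc["s0", "t0"] == pytest.approx(1.0)


class TestHierarchicalCluster:
    def test_hand_computable_three_sample_tree(self):
        profiles = pd.DataFrame(
            {"f": [0.0, 1.0, 10.0]}, index=["a", "b", "c"]
        )
        dend = es.hierarchical_cluster(profiles)
        heights = sorted(dend.merge_heights())
        assert heights[0] == pytest.approx(1.0)
        assert heights[1] == pytest.approx((10.0 + 9.0) / 2)  # average linkage
        newick = dend.to_newick()
        assert newick.startswith("((a:") or "(a:" in newick
        assert newick.count(",") == 2

    def test_duplicate_sample_merges_first_at_zero(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=["a", "a_copy", "c"]
        )
        dend = es.hierarchical_cluster(profiles)
        assert min(dend.merge_heights()) == 0.0

    def test_merge_sequence_matches_naive_oracle(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            pts = rng.normal(size=(8, 5))
            labels = [f"s{j}" for j in range(8)]
            dend = es.hierarchical_cluster(pd.DataFrame(pts, index=labels))
            merges = upgma_oracle(pts, labels)
            assert np.allclose(
                sorted(dend.merge_heights()),
                sorted(h for _, _, h in merges),
                atol=1e-9,
            )
            # same final top split
            top_a, top_b, _ = merges[-1]
            newick = dend.to_newick()
            import re

            leaves = set(re.findall(r"([A-Za-z0-9_]+):", newick))
            assert set(labels) <= leaves

    def test_monotone_merge_heights(self):
        rng = np.random.default_rng(23)
        dend = es.hierarchical_cluster(
            pd.DataFrame(rng.normal(size=(10, 4)), index=[f"s{j}" for j in range(10)])
        )
        assert (np.diff(dend.merge_heights()) >= -1e-12).all()

    def test_nan_input_fatal_with_location(self):
        profiles = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]], index=["a", "b"])
        with pytest.raises(es.ValidationError, match="a"):
            es.hierarchical_cluster(profiles)

    def test_newick_parses_with_biopython(self, tmp_path):
        Phylo = pytest.importorskip("Bio.Phylo")
        rng = np.random.default_rng(5)
        labels = [f"s{j}" for j in range(6)]
        dend = es.hierarchical_cluster(pd.DataFrame(rng.normal(size=(6, 3)), index=labels))
        path = tmp_path / "tree.nwk"
        path.write_text(dend.to_newick() + "\n")
        tree = Phylo.read(str(path), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == labels
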