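import numpy as np
import pandas as pd
import pytest

import embryostage as es
from embryostage.network import shared_target_fraction


def small_panel():
    return es.MarkerPanel(icm=("M1",), primitive_endoderm=("M2",), te=("M3",))


def em_from_profiles(rows, stages=6):
    profiles = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"s{i}" for i in range(stages)]
    ).astype(float)
    return es.profiles_to_expression(profiles)


class TestBuildNetwork:
    def test_identical_profile_gets_weight_one_edge(self):
        prof = [1.0, 2.0, 1.5, 2.5, 1.2, 2.2]
        em = em_from_profiles({"M1": prof, "g_copy": prof,
                               "M2": [2, 1, 2, 1, 2, 1], "M3": [1, 1, 2, 2, 1, 2]})
        net = es.build_network(em, small_panel(), threshold=0.9, expression_floor=3.0)
        assert net.graph.has_edge("M1", "g_copy")
        assert net.graph["M1"]["g_copy"]["weight"] == pytest.approx(1.0)

    def test_anticorrelated_profile_linked_by_absolute_value(self):
        prof = np.array([1.0, 2.0, 1.5, 2.5, 1.2, 2.2])
        mirror = (3.5 - prof).tolist()
        em = em_from_profiles({"M1": prof.tolist(), "g_mirror": mirror,
                               "M2": [2, 1, 2, 1, 2, 1.0], "M3": [1, 1, 2, 2, 1, 2.0]})
        net = es.build_network(em, small_panel(), threshold=0.9)
        assert net.graph.has_edge("M1", "g_mirror")

    def test_uncorrelated_profile_not_linked(self):
        em = em_from_profiles(
            {"M1": [1, 2, 1, 2, 1, 2.0], "g_flatline": [1.5, 1.5, 1.6, 1.5, 1.6, 1.5],
             "M2": [2, 1, 2, 1, 2, 1.0], "M3": [1, 1, 2, 2, 1, 2.0]}
        )
        net = es.build_network(em, small_panel(), threshold=0.9)
        assert not net.graph.has_edge("M1", "g_flatline")

    def test_expression_floor_excludes_silent_genes(self):
        prof = [1.0, 2.0, 1.5, 2.5, 1.2, 2.2]
        silent = [p - 2.0 for p in prof]  # same shape, max RPKM < 3
        em = em_from_profiles({"M1": prof, "g_silent": silent,
                               "M2": [2, 1, 2, 1, 2, 1.0], "M3": [1, 1, 2, 2, 1, 2.0]})
        net = es.build_network(em, small_panel(), threshold=0.9)
        assert "g_silent" not in net.graph

    def test_threshold_monotone_pruning(self):
        panel = es.MarkerPanel.default()
        profiles, _ = es.simulate_marker_network(panel.all_markers, n_noise=50, seed=3)
        em = es.profiles_to_expression(profiles)
        edges = {}
        for thr in (0.85, 0.9, 0.95):
            net = es.build_network(em, panel, threshold=thr)
            edges[thr] = set(map(frozenset, net.graph.edges()))
        assert edges[0.95] <= edges[0.9] <= edges[0.85]

    def test_planted_module_recovery_f1(self):
        panel = es.MarkerPanel.default()
        profiles, truth = es.simulate_marker_network(panel.all_markers, seed=19)
        em = es.profiles_to_expression(profiles)
        net = es.build_network(em, panel, threshold=0.9)
        markers = set(panel.all_markers)
        called = {
            (u, v) if u in markers else (v, u) for u, v in net.graph.edges()
        }
        tp = len(called & truth)
        f1 = 2 * tp / (2 * tp + len(called - truth) + len(truth - called))
        assert f1 >= 0.95

    def test_affine_rescaling_invariance(self):
        prof = np.array([1.0, 2.0, 1.5, 2.5, 1.2, 2.2])
        em1 = em_from_profiles({"M1": prof.tolist(), "g": (0.6 * prof + 0.3).tolist(),
                                "M2": [2, 1, 2, 1, 2, 1.0], "M3": [1, 1, 2, 2, 1, 2.0]})
        net = es.build_network(em1, small_panel(), threshold=0.9)
        assert net.graph["M1"]["g"]["weight"] == pytest.approx(1.0)


class TestRemoveSingletons:
    def build(self, target_sets):
        graph_em = {}
        base = np.array([1.0, 2.0, 1.4, 2.4, 1.1, 2.1])
        shift = {"M1": 0.0, "M2": 0.011, "M3": 0.022}
        rng = np.random.default_rng(0)
        # distinct but perfectly-correlating profiles per marker module
        profiles = {}
        for m, targets in target_sets.items():
            prof = base + shift[m] + rng.normal(0, 1e-6, 6)
            profiles[m] = prof
            for t in targets:
                profiles[t] = prof
        # decorrelate different markers' modules by permuting stages
        perms = {"M1": [0, 1, 2, 3, 4, 5], "M2": [0, 2, 4, 1, 5, 3], "M3": [3, 5, 0, 4, 2, 1]}
        rows = {}
        for m, targets in target_sets.items():
            for g in [m, *targets]:
                rows[g] = profiles[g][perms[m]]
        em = em_from_profiles(rows)
        return es.build_network(em, small_panel(), threshold=0.9)

    def test_identical_target_sets_nothing_removed(self):
        prof = [1.0, 2.0, 1.4, 2.4, 1.1, 2.1]
        other = [2.0, 1.0, 2.4, 1.4, 2.1, 1.0]
        em = em_from_profiles({
            "M1": prof, "M2": prof, "M3": other,
            "t1": prof, "t2": prof, "t3": other,
        })
        net = es.build_network(em, small_panel(), threshold=0.9)
        pruned = es.remove_singletons(net, 0.05)
        assert net.graph.nodes  # sanity
        assert "M1" in pruned.graph and "M2" in pruned.graph

    def test_isolated_marker_removed_with_exclusive_targets(self):
        prof = [1.0, 2.0, 1.4, 2.4, 1.1, 2.1]
        lonely = [1.0, 1.0, 2.4, 1.1, 2.2, 1.6]
        em = em_from_profiles({
            "M1": prof, "M2": prof, "M3": lonely,
            "shared": prof, "only3": lonely,
        })
        net = es.build_network(em, small_panel(), threshold=0.9)
        assert net.graph.has_edge("M3", "only3")
        pruned = es.remove_singletons(net, 0.05)
        assert "M3" not in pruned.graph and "only3" not in pruned.graph
        assert pruned.graph.has_edge("M1", "shared")

    def test_crafted_fractions_against_brute_force(self):
        """Shared fractions {0.5, 0.04, 0.04}: only the low-overlap marker goes."""
        t1 = [f"a{i}" for i in range(10)] + [f"ab{i}" for i in range(10)]
        t2 = [f"b{i}" for i in range(10)] + [f"ab{i}" for i in range(10)]
        t3 = [f"c{i}" for i in range(24)] + ["a0"]
        graph = __import__("networkx").Graph()
        for m, ts in (("M1", t1), ("M2", t2), ("M3", t3)):
            graph.add_node(m, group="marker", hub=True)
            for t in ts:
                graph.add_edge(m, t, weight=0.95)
        net = es.CoexpressionNetwork(graph=graph, markers=("M1", "M2", "M3"))
        targets = net.target_sets()
        # brute-force pairwise enumeration of shared fractions
        fracs = {
            m: max(
                len(targets[m] & targets[o]) / min(len(targets[m]), len(targets[o]))
                for o in targets
                if o != m
            )
            for m in targets
        }
        assert fracs["M1"] == pytest.approx(0.5)
        assert fracs["M3"] == pytest.approx(1 / 20)
        pruned = es.remove_singletons(net, min_shared_fraction=0.06)
        assert "M3" not in pruned.graph
        assert "M1" in pruned.graph and "M2" in pruned.graph
        # a0 is shared with M1, so it survives; c* targets are exclusive
        assert "a0" in pruned.graph and "c0" not in pruned.graph

    def test_idempotent(self):
        panel = es.MarkerPanel.default()
        profiles, _ = es.simulate_marker_network(panel.all_markers, n_noise=100, seed=8)
        em = es.profiles_to_expression(profiles)
        net = es.build_network(em, panel, threshold=0.9)
        once = es.remove_singletons(net, 0.05)
        twice = es.remove_singletons(once, 0.05)
        assert set(once.graph.nodes) == set(twice.graph.nodes)
        assert set(map(frozenset, once.graph.edges())) == set(
            map(frozenset, twice.graph.edges())
        )

    def test_single_marker_network_empties_with_warning(self):
        graph = __import__("networkx").Graph()
        graph.add_edge("M1", "t1", weight=0.95)
        net = es.CoexpressionNetwork(graph=graph, markers=("M1",))
        pruned = es.remove_singletons(net)
        assert pruned.graph.number_of_nodes() == 0

    def test_denominator_conventions(self):
        a, b = {"x", "y", "z"}, {"x"}
        assert shared_target_fraction(a, b, "min") == 1.0
        assert shared_target_fraction(a, b, "union") == pytest.approx(1 / 3)


class TestExport:
    def build_net(self):
        panel = es.MarkerPanel.default()
        profiles, _ = es.simulate_marker_network(
            panel.all_markers[:5], n_targets=4, n_noise=10, seed=2
        )
        em = es.profiles_to_expression(profiles)
        return es.build_network(
            em,
            es.MarkerPanel(
                icm=tuple(panel.all_markers[:3]),
                primitive_endoderm=(panel.all_markers[3],),
                te=(panel.all_markers[4],),
            ),
            threshold=0.9,
        )

    @pytest.mark.parametrize("fmt", ["edgelist", "graphml"])
    def test_round_trip(self, tmp_path, fmt):
        from embryostage.network import read_network

        net = self.build_net()
        path = tmp_path / f"net.{fmt}"
        es.export_network(net, path, fmt)
        back = read_network(path, net.markers, fmt)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        for u, v, d in net.graph.edges(data=True):
            assert back.graph[u][v]["weight"] == pytest.approx(d["weight"])

    def test_empty_network_valid_file(self, tmp_path):
        import networkx as nx

        net = es.CoexpressionNetwork(graph=nx.Graph(), markers=())
        path = es.export_network(net, tmp_path / "empty.tsv")
        assert path.read_text().startswith("source\ttarget\tweight")

    def test_graphml_is_well_formed_xml(self, tmp_path):
        lxml_etree = pytest.importorskip("lxml.etree")
        net = self.build_net()
        path = tmp_path / "net.graphml"
        es.export_network(net, path, "graphml")
        root = lxml_etree.parse(str(path)).getroot()
        assert root.tag.endswith("graphml")
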