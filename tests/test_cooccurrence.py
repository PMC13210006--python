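import numpy as np
import pandas as pd
import pytest

from rhizonet.core_io import FeatureTable
from rhizonet.cooccurrence import (
    adjust_fdr,
    build_network,
    complexity_scores,
    spearman_matrix,
    topology_summary,
    treatment_subnetwork,
)
import networkx as nx


def _table(cols: dict) -> FeatureTable:
    df = pd.DataFrame(cols, index=[f"s{i}" for i in range(len(next(iter(cols.values()))))])
    return FeatureTable(df, mode="counts")


class TestSpearman:
    def test_perfect_monotone(self):
        t = _table({"x": [1, 2, 3, 4], "y": [10, 20, 30, 40], "z": [4, 3, 2, 1]})
        sm = spearman_matrix(t)
        assert sm.r.loc["x", "y"] == pytest.approx(1.0)
        assert sm.r.loc["x", "z"] == pytest.approx(-1.0)

    def test_ties_match_average_rank_pearson(self):
        x = [1, 2, 2, 4]
        y = [1, 3, 2, 4]
        t = _table({"x": x, "y": y})
        sm = spearman_matrix(t)
        # brute-force oracle: Pearson of the average-tie rank vectors
        rx = [1, 2.5, 2.5, 4]
        ry = [1, 3, 2, 4]
        expected = np.corrcoef(rx, ry)[0, 1]
        assert sm.r.loc["x", "y"] == pytest.approx(expected)

    def test_monotone_transform_invariance(self, rng):
        vals = rng.random((10, 3))
        t1 = FeatureTable(pd.DataFrame(vals, columns=list("abc")))
        t2 = FeatureTable(pd.DataFrame(np.exp(3 * vals), columns=list("abc")))
        pd.testing.assert_frame_equal(spearman_matrix(t1).r, spearman_matrix(t2).r)

    def test_zero_variance_taxon_excluded_with_warning(self):
        t = _table({"x": [1, 2, 3, 4], "y": [2, 1, 4, 3], "const": [5, 5, 5, 5]})
        with pytest.warns(UserWarning, match="const"):
            sm = spearman_matrix(t)
        assert "const" not in sm.taxa


class TestFdr:
    @pytest.mark.parametrize(
        "p_in, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.001, 1.0], [0.002, 1.0]),
        ],
    )
    def test_step_up_formula(self, p_in, expected):
        np.testing.assert_allclose(adjust_fdr(p_in), expected, atol=1e-12)

    def test_matches_brute_force_step_up(self, rng):
        p = rng.random(25)
        m = len(p)
        order = np.argsort(p)
        # independent oracle: p_adj(i) = min over j>=i of p(j)*m/j, capped
        sorted_adj = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(sorted_adj, 1.0)
        np.testing.assert_allclose(adjust_fdr(p), expected, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.2])


class TestBuildNetwork:
    def _sm(self, r, p_adj):
        taxa = ["a", "b"]
        rm = pd.DataFrame([[1.0, r], [r, 1.0]], index=taxa, columns=taxa)
        pm = pd.DataFrame([[0.0, p_adj], [p_adj, 0.0]], index=taxa, columns=taxa)
        from rhizonet.cooccurrence import SpearmanMatrix
        return SpearmanMatrix(r=rm, p_raw=pm, p_adj=pm)

    def test_passing_edge_present(self):
        g = build_network(self._sm(0.9, 0.001))
        assert g.has_edge("a", "b")
        assert g["a"]["b"]["sign"] == "+"

    def test_threshold_strictness(self):
        assert build_network(self._sm(0.70, 0.001)).number_of_edges() == 0
        assert build_network(self._sm(0.90, 0.01)).number_of_edges() == 0

    def test_all_below_threshold_empty(self):
        g = build_network(self._sm(0.3, 0.5))
        assert g.number_of_nodes() == 0

    def test_no_edge_violates_own_thresholds(self, default_dataset):
        table = default_dataset[0]
        g = build_network(spearman_matrix(table), 0.70, 0.01)
        for _, _, d in g.edges(data=True):
            assert abs(d["r"]) > 0.70
            assert d["p_adj"] < 0.01


class TestSubnetworks:
    def test_group_membership_and_inheritance(self, default_dataset):
        table, meta = default_dataset[0], default_dataset[1]
        g = build_network(spearman_matrix(table))
        groups = sorted({meta.treatment(s) for s in meta.sample_ids})
        union = set()
        for grp in groups:
            sub = treatment_subnetwork(g, table, meta, grp)
            union |= set(sub.nodes)
            for u, v, d in sub.edges(data=True):
                assert d == g[u][v]
        for grp in groups:
            assert set(treatment_subnetwork(g, table, meta, grp).nodes) <= union

    def test_absent_taxon_excluded(self, metadata18):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((18, 4)) + 0.5, index=metadata18.sample_ids,
                          columns=list("abcd"))
        df.loc[[s for s in df.index if s.startswith("NT")], "d"] = 0.0
        t = FeatureTable(df)
        g = nx.Graph()
        for u, v in [("a", "b"), ("c", "d")]:
            g.add_edge(u, v, r=0.9, p_raw=0.001, p_adj=0.001, sign="+")
        sub = treatment_subnetwork(g, t, metadata18, "NT")
        assert "d" not in sub.nodes
        full = treatment_subnetwork(g, t, metadata18, "MT")
        assert set(full.nodes) == {"a", "b", "c", "d"}

    def test_unknown_group_errors(self, default_dataset):
        table, meta = default_dataset[0], default_dataset[1]
        g = nx.Graph()
        with pytest.raises(KeyError):
            treatment_subnetwork(g, table, meta, "XX")


class TestTopology:
    def test_path_graph_hand_enumeration(self):
        g = nx.Graph()
        g.add_edge("A", "B", r=0.8)
        g.add_edge("B", "C", r=0.9)
        s = topology_summary(g)
        assert s.average_degree == pytest.approx(4 / 3)
        assert s.density == pytest.approx(2 / 3)
        assert s.average_path_length == pytest.approx(4 / 3)
        assert s.mean_betweenness_centrality == pytest.approx(1 / 3)
        assert s.positive_edge_proportion == 1.0

    def test_complete_graph(self):
        g = nx.complete_graph(4)
        nx.set_edge_attributes(g, 0.9, "r")
        s = topology_summary(g)
        assert s.density == pytest.approx(1.0)
        assert s.average_path_length == pytest.approx(1.0)
        assert s.clustering_coefficient == pytest.approx(1.0)

    def test_disconnected_uses_within_component_pairs(self):
        g = nx.Graph()
        g.add_edge("a", "b", r=0.9)
        g.add_edge("b", "c", r=0.9)
        g.add_edge("x", "y", r=-0.9)
        s = topology_summary(g)
        # pairs: (a,b)=1,(b,c)=1,(a,c)=2,(x,y)=1 -> mean 5/4
        assert s.average_path_length == pytest.approx(5 / 4)
        assert s.positive_edge_proportion == pytest.approx(2 / 3)

    def test_empty_and_tiny_graphs(self):
        s = topology_summary(nx.Graph())
        assert s.n_nodes == 0 and s.n_edges == 0
        g = nx.Graph()
        g.add_edge("a", "b", r=0.9)
        with pytest.warns(UserWarning):
            s2 = topology_summary(g)
        assert s2.n_nodes == 2


class TestComplexity:
    def test_identical_summaries_all_zero(self):
        df = pd.DataFrame({"average_degree": [2.0, 2.0], "density": [0.5, 0.5]},
                          index=["a", "b"])
        with pytest.warns(UserWarning):
            scores = complexity_scores(df)
        assert (scores["complexity"] == 0).all()

    def test_scores_centered(self, rng):
        df = pd.DataFrame(rng.random((5, 4)),
                          columns=["average_degree", "density",
                                   "average_path_length", "modularity"])
        scores = complexity_scores(df)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-9)

    def test_denser_regime_scores_higher(self):
        # planted high/low connectivity: denser subnetworks must order above
        rows = []
        for label, nn, ne in [("lo1", 20, 25), ("lo2", 22, 28),
                              ("hi1", 20, 80), ("hi2", 22, 90)]:
            rows.append({"label": label, "n_nodes": nn, "n_edges": ne,
                         "average_degree": 2 * ne / nn,
                         "density": 2 * ne / (nn * (nn - 1)),
                         "positive_edge_proportion": 0.8,
                         "average_path_length": 3.0 if ne < 50 else 1.8,
                         "mean_betweenness_centrality": 0.1,
                         "modularity": 0.6 if ne < 50 else 0.3,
                         "clustering_coefficient": 0.2 if ne < 50 else 0.5})
        df = pd.DataFrame(rows).set_index("label")
        with pytest.warns(UserWarning):
            scores = complexity_scores(df)
        assert min(scores.loc[["hi1", "hi2"], "complexity"]) > \
            max(scores.loc[["lo1", "lo2"], "complexity"])


def test_null_fdr_proportion_controlled():
    """Independent taxa: pairs passing p_adj < 0.05 average below 5%."""
    rates = []
    rng = np.random.default_rng(123)
    for rep in range(60):
        vals = rng.lognormal(0.0, 1.0, size=(18, 30))
        t = FeatureTable(pd.DataFrame(vals, columns=[f"t{j}" for j in range(30)]))
        sm = spearman_matrix(t)
        iu = np.triu_indices(len(sm.taxa), k=1)
        rates.append(np.mean(sm.p_adj.to_numpy()[iu] < 0.05))
    assert np.mean(rates) <= 0.05
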