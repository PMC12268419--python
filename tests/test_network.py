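"""Sparse-PLS integration, edge filtering, communities, and centrality."""

import itertools

import igraph as ig
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from isletnet.containers import OmicsMatrix, ValidationError
from isletnet.network import (
    AssociationNetwork,
    assemble_network,
    association_matrix,
    detect_communities,
    edge_filter,
    eigenvector_centrality,
    fit_pls_pair,
    modularity,
    rsd_cap_select,
)


def om(values, layer="metabolite", prefix="f", samples=None):
    values = np.asarray(values, dtype=float)
    idx = [f"{prefix}{i}" for i in range(values.shape[0])]
    cols = samples or [f"s{j}" for j in range(values.shape[1])]
    return OmicsMatrix(layer, pd.DataFrame(values, index=idx, columns=cols))


def graph_from_edges(edges, n=None):
    """AssociationNetwork from (i, j, w) triples over integer nodes."""
    nodes = sorted({i for e in edges for i in e[:2]} | set(range(n or 0)))
    g = ig.Graph()
    g.add_vertices(len(nodes))
    g.vs["name"] = [f"n{i}" for i in nodes]
    g.vs["layer"] = ["rna"] * len(nodes)
    g.add_edges([(e[0], e[1]) for e in edges])
    g.es["weight"] = [float(e[2]) for e in edges]
    g.es["p"] = [0.01] * len(edges)
    return AssociationNetwork(graph=g, condition="test")


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition


class TestRsdCap:
    def test_floor_arithmetic_and_selection(self, rng):
        vals = rng.uniform(1, 10, size=(10, 6))
        m = om(vals)
        out = rsd_cap_select(m, 0.3)
        assert out.n_features == 3
        rsd = m.values.std(axis=1, ddof=1) / m.values.mean(axis=1).abs()
        expected = set(rsd.sort_values(ascending=False).index[:3])
        assert set(out.feature_ids) == expected

    def test_preserves_input_order(self, rng):
        m = om(rng.uniform(1, 10, size=(10, 6)))
        out = rsd_cap_select(m, 0.5)
        positions = [m.feature_ids.index(f) for f in out.feature_ids]
        assert positions == sorted(positions)

    def test_zero_mean_features_excluded(self):
        vals = np.array([[1.0, -1.0, 1.0, -1.0], [2.0, 3.0, 4.0, 5.0], [1.0, 1.0, 2.0, 2.0]])
        out = rsd_cap_select(om(vals, layer="protein"), 0.67)
        assert "f0" not in out.feature_ids

    def test_all_zero_means_rejected(self):
        with pytest.raises(ValidationError):
            rsd_cap_select(om([[1.0, -1.0], [2.0, -2.0]], layer="protein"), 0.3)


class TestPlsPair:
    def test_selfpredicting_single_feature(self, rng):
        x = OmicsMatrix("protein", pd.DataFrame(rng.normal(size=(1, 8)), index=["x0"]))
        y = OmicsMatrix("protein", x.values.copy())
        model = fit_pls_pair(x, y)
        assert model.n_components >= 1
        assert model.q2[0] > 0.9

    def test_pure_noise_stops_at_one_component(self, rng):
        stopped = []
        for _ in range(20):
            x = OmicsMatrix("protein", pd.DataFrame(rng.normal(size=(15, 8)),
                            index=[f"x{i}" for i in range(15)]))
            y = OmicsMatrix("protein", pd.DataFrame(rng.normal(size=(12, 8)),
                            index=[f"y{i}" for i in range(12)]))
            stopped.append(fit_pls_pair(x, y).n_components)
        assert np.mean(np.array(stopped) == 1) >= 0.9

    def test_max_components_honored(self, rng):
        # strongly multi-factor data still respects the ceiling
        z = rng.standard_normal((12, 12))
        x = OmicsMatrix("protein", pd.DataFrame((z @ rng.normal(size=(12, 30))).T))
        y = OmicsMatrix("protein", pd.DataFrame((z @ rng.normal(size=(12, 25))).T))
        model = fit_pls_pair(x, y, max_components=10)
        assert model.n_components <= 10

    def test_requires_three_shared_samples(self, rng):
        x = OmicsMatrix("protein", pd.DataFrame(rng.normal(size=(3, 2)), columns=["a", "b"]))
        y = OmicsMatrix("protein", pd.DataFrame(rng.normal(size=(3, 2)), columns=["a", "b"]))
        with pytest.raises(ValidationError):
            fit_pls_pair(x, y)


class TestAssociationMatrix:
    def test_single_feature_identity(self, rng):
        vals = pd.DataFrame(rng.normal(size=(1, 8)), index=["x0"])
        x = OmicsMatrix("protein", vals)
        y = OmicsMatrix("protein", vals.copy())
        model = fit_pls_pair(x, y)
        scores = association_matrix(model, x, y)
        assert scores.iloc[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_equals_pearson_on_rank_one_data(self, rng):
        t = rng.standard_normal(30)
        a, b = rng.normal(size=12), rng.normal(size=9)
        x = OmicsMatrix("protein", pd.DataFrame(np.outer(a, t)))
        y = OmicsMatrix("protein", pd.DataFrame(np.outer(b, t)))
        model = fit_pls_pair(x, y)
        scores = association_matrix(model, x, y).to_numpy()
        pear = np.sign(np.outer(a, b))  # rank-1 noiseless: correlations are +-1
        assert np.max(np.abs(scores - pear)) < 1e-6

    def test_equals_pearson_on_full_rank_toy(self, rng):
        # shared 4-factor data: once the variates span the X column space,
        # the association scores reduce exactly to Pearson correlations
        n, k = 12, 4
        z = rng.standard_normal((n, k))
        x = OmicsMatrix("protein", pd.DataFrame((z @ rng.normal(size=(k, 6))).T))
        y = OmicsMatrix("protein", pd.DataFrame((z @ rng.normal(size=(k, 5))).T))
        model = fit_pls_pair(x, y, max_components=10)
        assert model.n_components >= k
        scores = association_matrix(model, x, y).to_numpy()
        xs = sps.zscore(x.values.to_numpy(), axis=1, ddof=1)
        ys = sps.zscore(y.values.to_numpy(), axis=1, ddof=1)
        pear = xs @ ys.T / (n - 1)
        assert np.max(np.abs(scores - pear)) < 1e-6

    def test_orthogonal_blocks_have_small_scores(self, rng):
        n = 300
        x = OmicsMatrix("protein", pd.DataFrame(rng.normal(size=(5, n))))
        y = OmicsMatrix("protein", pd.DataFrame(rng.normal(size=(5, n))))
        model = fit_pls_pair(x, y)
        scores = association_matrix(model, x, y).to_numpy()
        assert np.max(np.abs(scores)) < 0.2


class TestEdgeFilter:
    def test_threshold_and_p_rules(self):
        scores = pd.DataFrame([[0.5, 0.9, 0.4]], index=["a"], columns=["b1", "b2", "b3"])
        edges = edge_filter(scores, n_samples=10, threshold=0.5, alpha=0.05)
        # r=0.5 at n=10: t=1.633, p~0.141 -> rejected; r=0.9 -> p~4e-4 kept
        assert edges["target"].tolist() == ["b2"]
        assert edges["p"].iloc[0] == pytest.approx(2 * sps.t.sf(0.9 * np.sqrt(8 / (1 - 0.81)), 8), rel=1e-9)
        assert edges["p"].iloc[0] < 5e-4

    def test_perfect_correlation_p_zero(self):
        scores = pd.DataFrame([[1.0]], index=["a"], columns=["b"])
        edges = edge_filter(scores, n_samples=5)
        assert edges["p"].iloc[0] == 0.0

    def test_negative_scores_kept_signed(self):
        scores = pd.DataFrame([[-0.95]], index=["a"], columns=["b"])
        edges = edge_filter(scores, n_samples=10)
        assert edges["weight"].iloc[0] == -0.95


class TestAssembleNetwork:
    def test_empty_edge_lists_give_empty_network(self):
        empty = pd.DataFrame(columns=["source", "target", "weight", "p"])
        net = assemble_network({("rna", "protein"): empty})
        assert net.graph.vcount() == 0 and net.graph.ecount() == 0

    def test_union_graph_and_layer_tags(self):
        e1 = pd.DataFrame({"source": ["g1"], "target": ["p1"], "weight": [0.9], "p": [0.001]})
        e2 = pd.DataFrame({"source": ["g1"], "target": ["m1"], "weight": [-0.8], "p": [0.01]})
        net = assemble_network({("rna", "protein"): e1, ("rna", "metabolite"): e2})
        nodes = net.nodes_table()
        assert nodes.loc["g1", "layer"] == "rna"
        assert nodes.loc["m1", "layer"] == "metabolite"
        assert net.graph.ecount() == 2
        # all edges are inter-layer
        for e in net.graph.es:
            assert net.graph.vs[e.source]["layer"] != net.graph.vs[e.target]["layer"]

    def test_intra_layer_block_rejected(self):
        e = pd.DataFrame({"source": ["g1"], "target": ["g2"], "weight": [0.9], "p": [0.01]})
        with pytest.raises(ValidationError):
            assemble_network({("rna", "rna"): e})


class TestCommunities:
    def test_two_triangles_modularity_half(self):
        edges = [(0, 1, 1), (1, 2, 1), (0, 2, 1), (3, 4, 1), (4, 5, 1), (3, 5, 1)]
        net = graph_from_edges(edges)
        labels = detect_communities(net, seed=0)
        assert labels.nunique() == 2
        assert labels["n0"] == labels["n1"] == labels["n2"]
        assert modularity(net, labels) == pytest.approx(0.5)

    def test_complete_graph_single_community(self):
        edges = [(i, j, 1.0) for i, j in itertools.combinations(range(5), 2)]
        labels = detect_communities(graph_from_edges(edges), seed=0)
        assert labels.nunique() == 1

    @pytest.mark.parametrize(
        "edges,n",
        [
            ([(0, 1, 1), (1, 2, 1), (0, 2, 1), (3, 4, 1), (4, 5, 1), (3, 5, 1), (2, 3, 0.2)], 6),
            ([(0, 1, 1), (1, 2, 1), (0, 2, 1), (2, 3, 1), (3, 4, 1), (4, 5, 1), (3, 5, 1)], 6),
            ([(i, j, 1.0) for i, j in itertools.combinations(range(4), 2)]
             + [(i + 4, j + 4, 1.0) for i, j in itertools.combinations(range(4), 2)]
             + [(0, 4, 0.5)], 8),
        ],
    )
    def test_matches_exhaustive_modularity_search(self, edges, n):
        net = graph_from_edges(edges, n=n)
        labels = detect_communities(net, seed=0)
        found = modularity(net, labels)
        best = max(
            modularity(net, [next(k for k, grp in enumerate(part) if i in grp) for i in range(n)])
            for part in set_partitions(list(range(n)))
        )
        assert found == pytest.approx(best, abs=1e-9)

    def test_deterministic_under_seed(self, default_study):
        edges = [(0, 1, 0.9), (1, 2, 0.8), (0, 2, 0.7), (3, 4, 0.9), (4, 5, 0.6), (3, 5, 0.9), (1, 4, 0.3)]
        a = detect_communities(graph_from_edges(edges), seed=3)
        b = detect_communities(graph_from_edges(edges), seed=3)
        assert a.tolist() == b.tolist()


class TestEigenvectorCentrality:
    def test_star_analytic_values(self):
        edges = [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)]
        cent = eigenvector_centrality(graph_from_edges(edges))
        assert cent["n0"] == pytest.approx(1.0)
        for leaf in ("n1", "n2", "n3"):
            assert cent[leaf] == pytest.approx(1 / np.sqrt(3), abs=1e-9)

    def test_complete_graph_uniform(self):
        edges = [(i, j, 1.0) for i, j in itertools.combinations(range(4), 2)]
        cent = eigenvector_centrality(graph_from_edges(edges))
        assert np.allclose(cent.to_numpy(), 1.0)

    def test_matches_dense_eigendecomposition(self, rng):
        # random weighted graph, one component: compare to numpy principal vector
        n = 12
        edges = []
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.4:
                edges.append((i, j, float(rng.uniform(0.2, 1.0)) * (1 if rng.random() < 0.7 else -1)))
        edges += [(i, i + 1, 0.5) for i in range(n - 1)]  # ensure connected
        net = graph_from_edges(edges, n=n)
        cent = eigenvector_centrality(net)
        adj = np.zeros((n, n))
        for e in net.graph.es:
            w = abs(e["weight"])
            adj[e.source, e.target] = adj[e.target, e.source] = w
        vals, vecs = np.linalg.eigh(adj)
        principal = np.abs(vecs[:, np.argmax(vals)])
        principal /= principal.max()
        assert np.max(np.abs(cent.to_numpy() - principal)) < 1e-8

    def test_bipartite_component_converges(self):
        edges = [(0, 1, 1.0), (0, 2, 1.0), (1, 3, 1.0), (2, 3, 1.0)]  # 4-cycle (bipartite)
        cent = eigenvector_centrality(graph_from_edges(edges))
        assert np.allclose(cent.to_numpy(), 1.0)

    def test_adding_edge_never_lowers_rank(self, rng):
        base = [(0, 1, 0.8), (1, 2, 0.7), (2, 3, 0.9), (3, 4, 0.6), (0, 2, 0.5)]
        net = graph_from_edges(base, n=5)
        before = eigenvector_centrality(net).rank(ascending=True)
        net2 = graph_from_edges(base + [(4, 0, 0.9)], n=5)
        after = eigenvector_centrality(net2).rank(ascending=True)
        assert after["n4"] >= before["n4"]

    def test_isolated_component_scaling(self):
        # dominant triangle at 1.0; weaker pair scaled by eigenvalue ratio
        edges = [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0), (3, 4, 0.5)]
        cent = eigenvector_centrality(graph_from_edges(edges, n=5))
        assert cent["n0"] == pytest.approx(1.0)
        assert cent["n3"] == pytest.approx(0.5 / 2.0)  # lambda pair / lambda triangle
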