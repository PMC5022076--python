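"""Signed adjacency, topological overlap, module detection, eigengenes and
hub metrics."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from neurocourse.experiment import make_sample_table, TimecourseExperiment
from neurocourse.network import (
    UNASSIGNED,
    build_network,
    detect_modules,
    hub_metrics,
    module_eigengene,
    pick_soft_threshold,
    scale_free_fit,
    signed_adjacency,
    topological_overlap,
)

from conftest import make_experiment


def _frame(mat, prefix="g"):
    idx = [f"{prefix}{i}" for i in range(mat.shape[0])]
    return pd.DataFrame(mat, index=idx, columns=[f"s{j}" for j in range(mat.shape[1])])


class TestSignedAdjacency:
    def test_extreme_correlations(self):
        rng = np.random.default_rng(80)
        x = rng.normal(size=21)
        mat = np.vstack([x, 2 * x + 1, -x])
        adj = signed_adjacency(_frame(mat), beta=6)
        assert adj.iloc[0, 1] == pytest.approx(1.0)
        assert adj.iloc[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(np.diag(adj), 1.0)

    def test_zero_correlation_soft_threshold_value(self):
        # cor = 0 -> a = 0.5 ** beta
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        adj = signed_adjacency(_frame(np.vstack([x, y])), beta=12)
        assert adj.iloc[0, 1] == pytest.approx(0.5**12)

    def test_zero_variance_gene_reported(self):
        mat = np.vstack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(ValueError, match="g1"):
            signed_adjacency(_frame(mat), beta=6)


class TestTopologicalOverlap:
    def test_three_node_hand_example(self):
        adj = pd.DataFrame(
            [[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        tom = topological_overlap(adj)
        # k_i = 1.0; TOM_12 = (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert tom.loc["a", "b"] == pytest.approx(0.5)
        assert np.allclose(np.diag(tom), 1.0)

    def test_identical_rows_with_unit_link_give_tom_one(self):
        adj = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        tom = topological_overlap(adj)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_bounds_on_random_signed_adjacencies(self):
        rng = np.random.default_rng(81)
        for _ in range(100):
            n = rng.integers(3, 12)
            cor = np.clip(rng.uniform(-1, 1, (n, n)), -1, 1)
            cor = (cor + cor.T) / 2
            np.fill_diagonal(cor, 1.0)
            adj = ((1 + cor) / 2) ** 6
            np.fill_diagonal(adj, 1.0)
            frame = pd.DataFrame(adj)
            tom = topological_overlap(frame).to_numpy()
            assert tom.min() >= -1e-12
            assert tom.max() <= 1 + 1e-12
            assert np.allclose(tom, tom.T)


class TestModules:
    def test_two_planted_orthogonal_modules_recovered(self):
        rng = np.random.default_rng(82)
        t = np.linspace(0, 1, 21)
        prof1, prof2 = np.sin(2 * np.pi * t), t - 0.5
        rows, truth = [], []
        for i in range(40):
            rows.append(prof1 * rng.uniform(0.5, 1.5))
            truth.append(0)
        for i in range(40):
            rows.append(prof2 * rng.uniform(0.5, 1.5))
            truth.append(1)
        adj = signed_adjacency(_frame(np.array(rows)), beta=6)
        tom = topological_overlap(adj)
        labels = detect_modules(tom, min_size=10, cut_height=0.9)
        assert (labels != UNASSIGNED).all()
        assert adjusted_rand_score(truth, labels) == 1.0
        # size-ordered palette: the (equal-size) modules use the first colors
        assert set(labels.unique()) == {"turquoise", "blue"}

    def test_identical_genes_form_single_module(self):
        rng = np.random.default_rng(83)
        prof = rng.normal(size=21)
        mat = np.tile(prof, (30, 1)) * rng.uniform(0.5, 2.0, (30, 1))
        adj = signed_adjacency(_frame(mat), beta=6)
        tom = topological_overlap(adj)
        labels = detect_modules(tom, min_size=5, cut_height=0.99)
        assert labels.nunique() == 1
        assert (labels == "turquoise").all()

    def test_min_size_larger_than_clusters_gives_all_grey(self):
        rng = np.random.default_rng(84)
        mat = rng.normal(size=(20, 21))
        adj = signed_adjacency(_frame(mat), beta=6)
        tom = topological_overlap(adj)
        labels = detect_modules(tom, min_size=50, cut_height=0.9)
        assert (labels == UNASSIGNED).all()


class TestEigengene:
    def _experiment(self, mat):
        return make_experiment(mat)

    def test_identical_genes_eigengene_is_shared_profile(self):
        rng = np.random.default_rng(85)
        prof = rng.normal(size=21)
        expr = self._experiment(np.tile(prof, (10, 1)))
        labels = pd.Series("turquoise", index=expr.signal.index)
        eig, fc = module_eigengene(expr, labels)
        z = (prof - prof.mean()) / prof.std(ddof=0)
        got = eig.loc["turquoise"].to_numpy()
        r = np.corrcoef(got, z)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_eigengene_maximizes_explained_variance(self):
        rng = np.random.default_rng(86)
        mat = rng.normal(size=(15, 21))
        expr = self._experiment(mat)
        labels = pd.Series("blue", index=expr.signal.index)
        eig, _ = module_eigengene(expr, labels)
        v = eig.loc["blue"].to_numpy()
        v = v / np.linalg.norm(v)
        sd = mat.std(axis=1, ddof=0, keepdims=True)
        Xs = (mat - mat.mean(axis=1, keepdims=True)) / sd
        var_pc = np.sum((Xs @ v) ** 2)
        for _ in range(50):
            w = rng.normal(size=21)
            w /= np.linalg.norm(w)
            assert np.sum((Xs @ w) ** 2) <= var_pc + 1e-9

    def test_planted_latent_trajectory_recovered(self):
        rng = np.random.default_rng(87)
        t = np.linspace(0, 1, 7)
        latent = np.sin(np.pi * t)
        per_sample = np.repeat(latent, 3)
        mat = np.array(
            [8 + rng.uniform(0.5, 1.5) * per_sample + rng.normal(0, 0.15, 21)
             for _ in range(30)]
        )
        expr = self._experiment(mat)
        labels = pd.Series("turquoise", index=expr.signal.index)
        eig, _ = module_eigengene(expr, labels)
        r = np.corrcoef(eig.loc["turquoise"], per_sample)[0, 1]
        assert abs(r) >= 0.95


def brute_force_betweenness(G: nx.Graph) -> dict:
    """Enumerate all shortest paths per pair; split counts across ties."""
    nodes = list(G.nodes)
    bt = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t))
        except nx.NetworkXNoPath:
            continue
        for p in paths:
            for v in p[1:-1]:
                bt[v] += 1.0 / len(paths)
    return bt


class TestHubMetrics:
    def test_path_graph_from_spearman_thresholding(self):
        """Two end genes each rank-correlate ~0.93 with the middle gene but
        only ~0.85 with each other: the rho>0.9 graph is the path 1-2-3,
        so degrees are (1,2,1) and betweenness is (0,1,0)."""
        n = 60
        mid = np.arange(n, dtype=float)
        a = mid.copy()
        a[0:20] = a[0:20][::-1]  # reversal block: Sum d^2 = 20*399/3
        b = mid.copy()
        b[40:60] = b[40:60][::-1]
        frame = _frame(np.vstack([a, mid, b]))
        from scipy.stats import spearmanr

        rho = spearmanr(frame.to_numpy().T).statistic
        assert rho[0, 1] > 0.9 and rho[1, 2] > 0.9 and rho[0, 2] < 0.9
        adj = signed_adjacency(frame, beta=6)
        hubs = hub_metrics(frame, adj, spearman_cut=0.9)
        assert list(hubs.metrics["degree"]) == [1.0, 2.0, 1.0]
        assert list(hubs.metrics["betweenness"]) == [0.0, 1.0, 0.0]

    def test_star_closed_form(self):
        """Star on 5 nodes: center degree 4 and betweenness C(4,2)=6 from
        enumerating shortest paths; leaves 0."""
        from neurocourse.network import graph_centralities

        G = nx.star_graph(4)
        cent = graph_centralities(G)
        assert cent.loc[0, "degree"] == 4
        assert cent.loc[0, "betweenness"] == pytest.approx(6.0)
        assert (cent.loc[1:, "betweenness"] == 0).all()
        brute = brute_force_betweenness(G)
        assert brute[0] == pytest.approx(6.0)

    def test_betweenness_matches_exhaustive_enumeration(self):
        from neurocourse.network import graph_centralities

        rng = np.random.default_rng(91)
        for _ in range(20):
            G = nx.gnp_random_graph(8, 0.35, seed=int(rng.integers(1 << 30)))
            cent = graph_centralities(G)
            brute = brute_force_betweenness(G)
            for v in G.nodes:
                assert cent.loc[v, "betweenness"] == pytest.approx(
                    brute[v], abs=1e-9
                )

    def test_connectivity_degree_and_top_sets(self):
        rng = np.random.default_rng(92)
        t = np.linspace(0, 1, 21)
        # 10 tightly correlated genes + 10 independent noise genes
        mat = np.vstack(
            [t * rng.uniform(0.8, 1.2) + rng.normal(0, 0.01, 21) for _ in range(10)]
            + [rng.normal(size=21) for _ in range(10)]
        )
        frame = _frame(mat)
        adj = signed_adjacency(frame, beta=6)
        hubs = hub_metrics(frame, adj, spearman_cut=0.9, hub_quantile=0.10)
        m = hubs.metrics
        assert (m["degree"] <= 19).all()
        assert (m["connectivity"] <= 19 + 1e-9).all()
        assert (m["betweenness"] <= 19 * 18 / 2).all()
        # ceil(0.1 * 20) = 2 members per top set
        assert all(len(v) == 2 for v in hubs.top.values())
        # the correlated block dominates degree
        assert set(hubs.top["degree"]) <= {f"g{i}" for i in range(10)}

    def test_metrics_invariant_to_gene_order(self):
        rng = np.random.default_rng(93)
        mat = rng.normal(size=(15, 21))
        frame = _frame(mat)
        adj = signed_adjacency(frame, beta=6)
        h1 = hub_metrics(frame, adj).metrics
        perm = rng.permutation(frame.index)
        frame2 = frame.loc[perm]
        h2 = hub_metrics(frame2, adj.loc[perm, perm]).metrics
        assert np.allclose(h1.loc[perm, "connectivity"], h2["connectivity"])
        assert np.allclose(h1.loc[perm, "betweenness"], h2["betweenness"])


class TestSoftThreshold:
    def test_single_value_grid_returned(self):
        rng = np.random.default_rng(94)
        frame = _frame(rng.normal(size=(30, 21)))
        beta, table = pick_soft_threshold(frame, beta_grid=(6,))
        assert beta == 6

    def test_r2_invariant_under_gene_reordering(self):
        rng = np.random.default_rng(95)
        frame = _frame(rng.normal(size=(40, 21)))
        adj = signed_adjacency(frame, beta=6).to_numpy()
        k = adj.sum(axis=1) - 1
        r2a = scale_free_fit(k)
        r2b = scale_free_fit(np.random.default_rng(1).permutation(k))
        assert r2a == pytest.approx(r2b)

    def test_scale_free_network_reaches_r2(self):
        """Connectivity drawn from a power law: the fit detects it."""
        rng = np.random.default_rng(96)
        k = (rng.pareto(2.0, size=3000) + 1) * 2
        assert scale_free_fit(k) >= 0.8
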