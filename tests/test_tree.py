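"""Tree learning: structure invariants, branch decomposition, merging,
pseudotime, stability."""

import inspect

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from phenotree.tree import (
    TreeModel,
    assign_branches,
    compute_pseudotime,
    decompose_branches,
    fit_ddrtree,
    kruskal_mst,
    merge_branches,
    stability_ari,
)

from conftest import make_star


def brute_force_mst(points: np.ndarray) -> np.ndarray:
    """Independent exhaustive Kruskal on squared distances."""
    k = len(points)
    edges = sorted(
        (float(np.sum((points[i] - points[j]) ** 2)), i, j)
        for i in range(k) for j in range(i + 1, k)
    )
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    adj = np.zeros((k, k), dtype=bool)
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            adj[i, j] = adj[j, i] = True
    return adj


class TestFit:
    def test_default_centroid_count_is_2000(self):
        sig = inspect.signature(fit_ddrtree)
        assert sig.parameters["n_centroids"].default == 2000

    def test_collinear_data_yields_path(self):
        t = np.linspace(0, 1, 50)
        direction = np.random.default_rng(0).normal(size=10)
        X = np.outer(t, direction)
        m = fit_ddrtree(X, n_centroids=10, seed=0, normalize="global")
        deg = m.B.sum(axis=0)
        assert (deg == 1).sum() == 2  # exactly two leaves
        assert m.objective_trace[-1] <= m.objective_trace[0]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_monotone_and_structure_valid(self, seed):
        X = np.random.default_rng(seed).normal(size=(120, 8))
        m = fit_ddrtree(X, n_centroids=25, seed=seed)
        m.validate()
        tr = m.objective_trace
        assert all(b <= a + 1e-9 * abs(a) for a, b in zip(tr, tr[1:]))

    def test_small_n_equals_brute_force_mst(self):
        """N<=12, K=N, sigma->0: learned backbone equals the exhaustive
        Kruskal MST of the embedded points."""
        for seed in range(3):
            X = np.random.default_rng(seed).normal(size=(12, 5))
            m = fit_ddrtree(X, n_centroids=12, sigma=1e-8, seed=seed)
            np.testing.assert_array_equal(m.B, brute_force_mst(m.Y))

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            fit_ddrtree(np.random.default_rng(0).normal(size=(30, 4)),
                        n_centroids=1)

    def test_nonfinite_input_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 4))
        X[3, 2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_ddrtree(X, n_centroids=5)

    def test_k_clamped_to_n_with_warning(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        with pytest.warns(UserWarning, match="clamping"):
            m = fit_ddrtree(X, n_centroids=50, seed=0)
        assert m.n_centroids == 20

    def test_rotation_equivariance_of_partition(self):
        """Orthogonal rotation of inputs leaves the phenogroup partition
        unchanged (same seed, scale-preserving normalization)."""
        X, _ = make_star(seed=3, n_per=60)
        rng = np.random.default_rng(7)
        Q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
        kw = dict(n_centroids=30, seed=3, normalize="global")
        a = merge_branches(assign_branches(fit_ddrtree(X, **kw)), 3)
        b = merge_branches(assign_branches(fit_ddrtree(X @ Q, **kw)), 3)
        assert adjusted_rand_score(a.phenogroup, b.phenogroup) == 1.0

    def test_assignment_rows_sum_to_one(self, star_tree):
        np.testing.assert_allclose(star_tree.R.sum(axis=1), 1.0,
                                   atol=1e-8)


class TestBranches:
    def _tree_from_graph(self, g: nx.Graph, coords: np.ndarray) -> TreeModel:
        k = g.number_of_nodes()
        B = nx.to_numpy_array(g, nodelist=range(k), dtype=bool)
        R = np.eye(k)
        return TreeModel(W=np.eye(coords.shape[1], 2), Z=coords.copy(),
                         Y=coords.copy(), B=B, R=R, hyperparams={})

    def test_path_graph_single_branch(self):
        g = nx.path_graph(6)
        coords = np.column_stack([np.arange(6.0), np.zeros(6)])
        m = assign_branches(self._tree_from_graph(g, coords))
        assert m.hyperparams["n_subbranches"] == 1

    def test_three_star_three_branches(self):
        g = nx.star_graph(3)  # hub 0 + three leaves
        coords = np.array([[0, 0], [1, 0], [0, 1], [-1, 0]], dtype=float)
        m = assign_branches(self._tree_from_graph(g, coords))
        assert m.hyperparams["n_subbranches"] == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_branch_count_matches_edge_partition_oracle(self, seed):
        """On random trees with K<=20 nodes, the number of sub-branches
        equals (#edges - #degree-2 nodes): each degree-2 node merges two
        edges of one maximal path."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(4, 21))
        g = nx.random_labeled_tree(k, seed=seed)
        coords = rng.normal(size=(k, 2))
        m = assign_branches(self._tree_from_graph(g, coords))
        n_deg2 = sum(1 for n in g.nodes if g.degree[n] == 2)
        assert m.hyperparams["n_subbranches"] == (k - 1) - n_deg2
        # decomposition is an exact edge partition
        paths = decompose_branches(g)
        seen = set()
        for p in paths:
            for e in zip(p, p[1:]):
                e = frozenset(e)
                assert e not in seen
                seen.add(e)
        assert len(seen) == k - 1


class TestMerge:
    def test_identity_cut(self, star_tree):
        n_br = star_tree.hyperparams["n_subbranches"]
        m = merge_branches(star_tree, n_groups=n_br)
        # labels unchanged up to renaming
        assert adjusted_rand_score(m.branch_id, m.phenogroup) == 1.0

    def test_default_is_six_groups(self):
        sig = inspect.signature(merge_branches)
        assert sig.parameters["n_groups"].default == 6

    def test_too_many_groups_rejected(self, star_tree):
        with pytest.raises(ValueError, match="exceeds"):
            merge_branches(star_tree,
                           star_tree.hyperparams["n_subbranches"] + 1)

    def test_closest_adjacent_branches_merge_first(self):
        """4-armed layout with one arm pair much closer together: cutting
        to 3 groups merges exactly that pair."""
        # hub at origin; arms to E, NNE (close to E), W, S
        nodes = [(0.0, 0.0)]
        arms = []
        dirs = [(1, 0), (0.9, 0.45), (-1, 0), (0, -1)]
        g = nx.Graph()
        for a, (dx, dy) in enumerate(dirs):
            prev = 0
            ids = []
            for step in (0.5, 1.0):
                nodes.append((dx * step, dy * step))
                idx = len(nodes) - 1
                g.add_edge(prev, idx)
                prev = idx
                ids.append(idx)
            arms.append(ids)
        coords = np.array(nodes)
        k = len(nodes)
        m = TreeModel(W=np.eye(2), Z=coords.copy(), Y=coords.copy(),
                      B=nx.to_numpy_array(g, nodelist=range(k), dtype=bool),
                      R=np.eye(k), hyperparams={})
        m = merge_branches(assign_branches(m), n_groups=3)
        lab = m.centroid_phenogroup
        assert lab[arms[0][1]] == lab[arms[1][1]]  # E merged with NNE
        assert lab[arms[2][1]] != lab[arms[0][1]]
        assert lab[arms[3][1]] != lab[arms[0][1]]


class TestPseudotime:
    def test_center_sample_near_zero(self, star_tree):
        m = compute_pseudotime(star_tree)
        center_samples = np.flatnonzero(
            m.sample_centroid == m.center_node)
        if len(center_samples):
            offs = np.linalg.norm(
                m.Z[center_samples] - m.Y[m.center_node], axis=1)
            np.testing.assert_allclose(
                m.pseudotime_global[center_samples], offs, atol=1e-9)
        assert (m.pseudotime_global >= 0).all()

    def test_path_graph_matches_dijkstra(self):
        k = 9
        coords = np.column_stack([np.arange(k, dtype=float), np.zeros(k)])
        g = nx.path_graph(k)
        B = nx.to_numpy_array(g, nodelist=range(k), dtype=bool)
        m = TreeModel(W=np.eye(2), Z=coords.copy(), Y=coords.copy(),
                      B=B, R=np.eye(k), hyperparams={})
        m = compute_pseudotime(m)
        center = m.center_node
        # unit edges: geodesic distance from the centre is |j - center|
        expected = np.abs(np.arange(k) - center)
        np.testing.assert_allclose(m.pseudotime_global, expected,
                                   atol=1e-9)

    def test_branch_pseudotime_monotone_along_paths(self, star_tree):
        m = compute_pseudotime(star_tree)
        g = m.tree_graph()
        dist = nx.single_source_dijkstra_path_length(
            g, m.center_node, weight="weight")
        # per branch, centroid-level pseudotime ordering follows geodesic
        for b in np.unique(m.centroid_branch):
            nodes = np.flatnonzero(m.centroid_branch == b)
            for n in nodes:
                samples = np.flatnonzero(
                    (m.branch_id == b) & (m.sample_centroid == n))
                if len(samples):
                    assert (m.pseudotime_branch[samples] >= 0).all()
        assert (m.pseudotime_branch >= 0).all()
        assert max(dist.values()) > 0


class TestStability:
    def test_bootstrap_ari_on_separated_star(self, star_data):
        X, _ = star_data
        res = stability_ari(X, n_boot=10, n_groups=3, seed=0,
                            n_centroids=60, normalize="global")
        assert res["median"] >= 0.8
        assert res["iqr_low"] <= res["median"] <= res["iqr_high"]

    def test_too_few_resamples_rejected(self, star_data):
        with pytest.raises(ValueError):
            stability_ari(star_data[0], n_boot=1)
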