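"""Tree-structured dimensionality reduction (reversed graph embedding).

Learns, jointly, a linear 2-D embedding of a feature matrix and a spanning
tree over K centroids in that embedding, by alternating minimization of

    ||X - W Z||_F^2  +  lambda * sum_{(k,k') in tree} ||y_k - y_k'||^2
        +  gamma * ( sum_i softmin_sigma_k ||z_i - y_k||^2 )

over the orthonormal basis W (d x 2), sample coordinates Z (2 x N),
centroids Y (2 x K), the spanning tree B (K x K binary adjacency) and the
soft sample-centroid assignments R (N x K, implicit in the softmin).  Each
block update is an exact minimizer, so the objective is monotone
non-increasing:

* B: minimum spanning tree over squared centroid distances (stable
  Kruskal, ties broken by (i, j) index order);
* R: Boltzmann/softmax of negative scaled distances with bandwidth sigma;
* W, Z, Y: closed-form linear-algebra solves (top eigenvectors of a
  reduced d x d problem, then two small linear systems).

From the fitted tree we derive sub-branches (maximal paths between
branch points/leaves), merged phenogroups (Ward clustering of sub-branch
mean coordinates, adjacency-constrained), and pseudotime (geodesic
distance along the tree from its center).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "TreeModel",
    "fit_ddrtree",
    "assign_branches",
    "merge_branches",
    "compute_pseudotime",
    "stability_ari",
    "kruskal_mst",
]


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class TreeModel:
    """Fitted tree-embedding state plus derived labels.

    Attributes
    ----------
    W : (d, 2) orthonormal inverse-mapping basis.
    Z : (N, 2) embedded sample coordinates ("dimension 1", "dimension 2").
    Y : (K, 2) centroid coordinates.
    B : (K, K) binary symmetric spanning-tree adjacency.
    R : (N, K) soft assignments; rows sum to 1.
    objective_trace : per-iteration objective values (non-increasing).
    branch_id : per-sample sub-branch label (after assign_branches).
    phenogroup : per-sample merged group label, 1-based
        (after merge_branches).
    pseudotime_global / pseudotime_branch : per-sample distances
        (after compute_pseudotime).
    """

    W: np.ndarray
    Z: np.ndarray
    Y: np.ndarray
    B: np.ndarray
    R: np.ndarray
    hyperparams: dict[str, Any]
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True
    centroid_branch: np.ndarray | None = None
    branch_id: np.ndarray | None = None
    phenogroup: np.ndarray | None = None
    centroid_phenogroup: np.ndarray | None = None
    pseudotime_global: np.ndarray | None = None
    pseudotime_branch: np.ndarray | None = None
    center_node: int | None = None

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    @property
    def n_centroids(self) -> int:
        return self.Y.shape[0]

    @property
    def sample_centroid(self) -> np.ndarray:
        """Index of each sample's argmax-assignment centroid."""
        return np.argmax(self.R, axis=1)

    def tree_graph(self) -> nx.Graph:
        """The centroid tree as a networkx graph with Euclidean edge
        lengths in embedding space."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_centroids))
        ii, jj = np.nonzero(np.triu(self.B))
        for i, j in zip(ii, jj):
            g.add_edge(int(i), int(j),
                       weight=float(np.linalg.norm(self.Y[i] - self.Y[j])))
        return g

    def validate(self) -> None:
        """Assert the structural invariants of a fitted model."""
        K = self.n_centroids
        if not np.array_equal(self.B, self.B.T):
            raise AssertionError("tree adjacency not symmetric")
        n_edges = int(self.B.sum()) // 2
        if n_edges != K - 1:
            raise AssertionError(f"tree has {n_edges} edges, expected {K-1}")
        g = self.tree_graph()
        if not nx.is_connected(g):
            raise AssertionError("tree is disconnected")
        if not np.allclose(self.R.sum(axis=1), 1.0, atol=1e-8):
            raise AssertionError("assignment rows do not sum to 1")
        wtw = self.W.T @ self.W
        if not np.allclose(wtw, np.eye(self.W.shape[1]), atol=1e-6):
            raise AssertionError("basis W not orthonormal")


# ---------------------------------------------------------------------------
# MST with deterministic tie-breaking
# ---------------------------------------------------------------------------

def kruskal_mst(dist: np.ndarray) -> np.ndarray:
    """Minimum spanning tree of a dense symmetric distance matrix.

    Kruskal's algorithm with edges sorted by (weight, i, j), so ties are
    broken by stable index order.  Returns a binary symmetric adjacency.
    """
    k = dist.shape[0]
    if k == 1:
        return np.zeros((1, 1), dtype=bool)
    ii, jj = np.triu_indices(k, 1)
    order = np.lexsort((jj, ii, dist[ii, jj]))
    parent = np.arange(k)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    adj = np.zeros((k, k), dtype=bool)
    n_edges = 0
    for e in order:
        a, b = find(int(ii[e])), find(int(jj[e]))
        if a != b:
            parent[a] = b
            adj[ii[e], jj[e]] = adj[jj[e], ii[e]] = True
            n_edges += 1
            if n_edges == k - 1:
                break
    return adj


def _sqdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances between rows of a and b."""
    d = (
        np.sum(a**2, axis=1)[:, None]
        + np.sum(b**2, axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    return np.maximum(d, 0.0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_ddrtree(
    X: np.ndarray,
    n_centroids: int = 2000,
    n_dims: int = 2,
    lam: float | None = None,
    sigma: float = 1e-3,
    gamma: float = 10.0,
    max_iter: int = 20,
    tol: float = 1e-3,
    seed: int = 0,
    normalize: str = "per-feature",
) -> TreeModel:
    """Fit the tree-structured embedding.

    Parameters
    ----------
    X : (N, d) feature matrix.  Features are standardized (zero mean, unit
        variance per column) before fitting unless ``standardized="true"``.
    n_centroids : int
        Number of tree nodes K (default 2000); clamped to N with a warning
        when N < K.
    n_dims : int
        Embedding dimension (default 2; larger values untested downstream).
    lam : float
        Tree-smoothness weight; default ``5 * N / K``.
    sigma : float
        Softmax assignment bandwidth (default 1e-3).
    gamma : float
        Assignment-term weight (default 10).
    max_iter, tol :
        Alternating-minimization stopping rule: relative objective change
        below ``tol`` or ``max_iter`` iterations.
    seed : int
        Seed for centroid initialization (sampling of distinct points).
    normalize : {"per-feature", "global", "none"}
        Input normalization.  "per-feature" (default) z-scores each
        column — the right choice for latent features on heterogeneous
        scales.  "global" centers columns and divides by one pooled scale,
        preserving relative feature variances — appropriate when features
        are already commensurate (z-scoring commensurate features only
        inflates low-variance noise directions).  "none" asserts the
        caller has normalized.

    Returns
    -------
    TreeModel
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("X must be 2-D with at least 3 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if n_centroids < 2:
        raise ValueError("need at least 2 centroids")
    N, d = X.shape
    if normalize == "per-feature":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    elif normalize == "global":
        mu = X.mean(axis=0)
        scale = X.std() or 1.0
        X = (X - mu) / scale
    elif normalize != "none":
        raise ValueError(f"unknown normalize mode {normalize!r}")
    K = n_centroids
    if K > N:
        warnings.warn(f"n_centroids={K} > N={N}; clamping to N")
        K = N
    lam = 5.0 * N / K if lam is None else lam
    rng = np.random.default_rng(seed)

    # init: PCA basis, embedded points, centroids = K distinct samples
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    W = vt[:n_dims].T  # (d, q)
    Z = X @ W  # (N, q)
    Y = Z[rng.choice(N, size=K, replace=False)].copy()

    XT = X.T  # (d, N)
    trace: list[float] = []
    converged = False
    B = kruskal_mst(_sqdist(Y, Y))
    for it in range(max_iter):
        # --- B step: MST over squared centroid distances
        B = kruskal_mst(_sqdist(Y, Y))
        L = np.diag(B.sum(axis=0)) - B.astype(float)

        # --- objective with R at its optimum (softmin via logsumexp)
        distZY = _sqdist(Z, Y)
        softmin = -sigma * logsumexp(-distZY / sigma, axis=1)
        obj = (
            np.sum((X - Z @ W.T) ** 2)
            + lam * float(np.trace(Y.T @ L @ Y))
            + gamma * float(np.sum(softmin))
        )
        trace.append(obj)
        if it > 0 and abs(trace[-2] - trace[-1]) <= tol * abs(trace[-2]):
            converged = True
            break

        # --- R step (explicit, for the solves below)
        m = distZY.min(axis=1, keepdims=True)
        R = np.exp(-(distZY - m) / sigma)
        R /= R.sum(axis=1, keepdims=True)
        Gamma = R.sum(axis=0)  # (K,)

        # --- joint (W, Z, Y) solve given B, R
        A = (lam / gamma) * L + np.diag(Gamma)  # (K, K), SPD
        # Q = 1/(1+gamma) * (I_N + R A_t^{-1} R^T) with
        # A_t = ((gamma+1)/gamma) * A - R^T R
        At = ((gamma + 1.0) / gamma) * A - R.T @ R
        tmp = np.linalg.solve(At, R.T)  # (K, N)
        # C = X^T Q computed blockwise to avoid forming an N x N matrix
        XR = XT @ R  # (d, K)
        C = (XT + XR @ tmp) / (gamma + 1.0)  # (d, N)
        M = C @ X  # (d, d)
        evals, evecs = np.linalg.eigh((M + M.T) / 2.0)
        W = evecs[:, ::-1][:, :n_dims]
        Z = (W.T @ C).T  # (N, q)
        Y = np.linalg.solve(A, R.T @ Z)  # (K, q)

    if not converged:
        warnings.warn("tree fit did not converge; returning best iterate")

    distZY = _sqdist(Z, Y)
    m = distZY.min(axis=1, keepdims=True)
    R = np.exp(-(distZY - m) / sigma)
    R /= R.sum(axis=1, keepdims=True)
    B = kruskal_mst(_sqdist(Y, Y))

    model = TreeModel(
        W=W, Z=Z, Y=Y, B=B, R=R,
        hyperparams={
            "n_centroids": K, "n_dims": n_dims, "lambda": lam,
            "sigma": sigma, "gamma": gamma, "max_iter": max_iter,
            "tol": tol, "seed": seed,
        },
        objective_trace=trace,
        converged=converged,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# branches, phenogroups, pseudotime
# ---------------------------------------------------------------------------

def decompose_branches(g: nx.Graph) -> list[list[int]]:
    """Partition a tree's edges into maximal paths between special nodes.

    Special nodes are leaves (degree 1) and branch points (degree >= 3);
    every maximal chain of degree-2 nodes between two special nodes is one
    sub-branch, returned as its ordered node list.
    """
    if g.number_of_nodes() == 1:
        return [[next(iter(g.nodes))]]
    special = [n for n in g.nodes if g.degree[n] != 2]
    if not special:  # cycle-free connected graph always has leaves
        raise ValueError("input graph is not a tree")
    paths: list[list[int]] = []
    seen_edges: set[frozenset] = set()
    for s in sorted(special):
        for nb in sorted(g.neighbors(s)):
            if frozenset((s, nb)) in seen_edges:
                continue
            path = [s, nb]
            while g.degree[path[-1]] == 2:
                nxt = [x for x in g.neighbors(path[-1]) if x != path[-2]][0]
                path.append(nxt)
            for a, b in zip(path, path[1:]):
                seen_edges.add(frozenset((a, b)))
            paths.append(path)
    return paths


def assign_branches(model: TreeModel) -> TreeModel:
    """Label each centroid and sample with its sub-branch.

    Branch points (degree >= 3) belong to every incident sub-branch; they
    are assigned the lowest-indexed incident branch for determinism.
    Samples inherit the sub-branch of their argmax-assignment centroid.
    """
    g = model.tree_graph()
    paths = decompose_branches(g)
    centroid_branch = np.full(model.n_centroids, -1, dtype=int)
    for b, path in enumerate(paths):
        for node in path:
            if centroid_branch[node] == -1:
                centroid_branch[node] = b
    model.centroid_branch = centroid_branch
    model.branch_id = centroid_branch[model.sample_centroid]
    model.hyperparams["n_subbranches"] = len(paths)
    return model


def merge_branches(model: TreeModel, n_groups: int = 6) -> TreeModel:
    """Merge sub-branches into ``n_groups`` phenogroups.

    Ward agglomerative clustering of the sub-branch mean coordinates in
    embedding space, constrained by sub-branch adjacency (branches sharing
    a tree node may merge), so merged groups stay contiguous on the tree
    whenever adjacency permits.  Phenogroup labels are 1-based.
    """
    if model.centroid_branch is None:
        assign_branches(model)
    g = model.tree_graph()
    paths = decompose_branches(g)
    n_br = len(paths)
    if n_groups > n_br:
        raise ValueError(
            f"n_groups={n_groups} exceeds the {n_br} sub-branches"
        )
    if n_groups == n_br:
        merged = np.arange(n_br)
    else:
        means = np.array([model.Y[p].mean(axis=0) for p in paths])
        conn = np.zeros((n_br, n_br), dtype=int)
        node_sets = [set(p) for p in paths]
        for a in range(n_br):
            for b in range(a + 1, n_br):
                if node_sets[a] & node_sets[b]:
                    conn[a, b] = conn[b, a] = 1
        clus = AgglomerativeClustering(
            n_clusters=n_groups, linkage="ward",
            connectivity=conn if conn.any() else None,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # connectivity warnings
            merged = clus.fit_predict(means)
    centroid_group = np.full(model.n_centroids, -1, dtype=int)
    for b, path in enumerate(paths):
        for node in path:
            if centroid_group[node] == -1:
                centroid_group[node] = merged[b]
    model.centroid_phenogroup = centroid_group + 1
    model.phenogroup = centroid_group[model.sample_centroid] + 1
    model.hyperparams["n_groups"] = int(n_groups)
    return model


def compute_pseudotime(model: TreeModel) -> TreeModel:
    """Geodesic pseudotime along the tree.

    The tree center is the centroid nearest the grand mean of the embedded
    coordinates.  Global pseudotime of a sample is the geodesic distance
    (edge lengths = Euclidean distances in embedding space) from the
    center to the sample's centroid, plus the sample's Euclidean offset to
    that centroid.  Branch pseudotime is measured from the branch's node
    nearest (in geodesic distance) to the center.
    """
    g = model.tree_graph()
    if not nx.is_connected(g):
        raise AssertionError("tree adjacency is disconnected")
    grand = model.Z.mean(axis=0)
    center = int(np.argmin(np.linalg.norm(model.Y - grand, axis=1)))
    dist_from_center = nx.single_source_dijkstra_path_length(
        g, center, weight="weight"
    )
    dc = np.array([dist_from_center[k] for k in range(model.n_centroids)])
    sc = model.sample_centroid
    offset = np.linalg.norm(model.Z - model.Y[sc], axis=1)
    model.pseudotime_global = dc[sc] + offset
    model.center_node = center

    if model.centroid_branch is None:
        assign_branches(model)
    # branch origin = the branch's node closest to the tree center
    paths = decompose_branches(g)
    pt_branch = np.zeros(model.n_samples)
    for b, path in enumerate(paths):
        origin = min(path, key=lambda n: (dc[n], n))
        d_origin = nx.single_source_dijkstra_path_length(
            g, origin, weight="weight"
        )
        mask = model.branch_id == b
        if mask.any():
            db = np.array([d_origin[k] for k in sc[mask]])
            pt_branch[mask] = db + offset[mask]
    model.pseudotime_branch = pt_branch
    return model


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

def stability_ari(
    X: np.ndarray,
    n_boot: int = 10,
    n_groups: int = 6,
    seed: int = 0,
    **fit_kwargs: Any,
) -> dict[str, float]:
    """Bootstrap stability of the phenogroup partition.

    Refits the tree on bootstrap resamples of the rows of ``X`` and
    computes the adjusted Rand index between the reference phenogroup
    labels and each resample's labels, on the samples present in both
    (unique resampled indices).

    Returns
    -------
    dict with ``median``, ``iqr_low``, ``iqr_high`` and the raw ``aris``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    ref = merge_branches(
        assign_branches(fit_ddrtree(X, seed=seed, **fit_kwargs)),
        n_groups=n_groups,
    )
    aris = []
    for b in range(n_boot):
        idx = rng.integers(0, X.shape[0], size=X.shape[0])
        uniq = np.unique(idx)
        mod = merge_branches(
            assign_branches(
                fit_ddrtree(X[uniq], seed=seed + 1 + b, **fit_kwargs)
            ),
            n_groups=n_groups,
        )
        aris.append(
            adjusted_rand_score(ref.phenogroup[uniq], mod.phenogroup)
        )
    q1, med, q3 = np.percentile(aris, [25, 50, 75])
    return {"median": float(med), "iqr_low": float(q1),
            "iqr_high": float(q3), "aris": [float(a) for a in aris]}
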