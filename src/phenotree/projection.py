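"""Projection of external cohorts onto a frozen reference tree.

New samples never refit the tree.  Their latent features are mapped to
tree coordinates by two independent gradient-boosted regressors (one per
embedding dimension) trained on the reference cohort, the raw predictions
are snapped to the nearest point on any tree edge (orthogonal projection
onto segments, minimum over edges), and phenogroups are assigned by a
k-nearest-neighbour vote among reference samples in coordinate space.
The neighbour count k is selected by 10-fold cross-validation over a
1–200 grid on macro F1 (precision/recall reported alongside).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, mean_absolute_error, r2_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from xgboost import XGBRegressor

from .tree import TreeModel

__all__ = ["ProjectionModel", "fit_projection", "project_cohort",
           "snap_to_tree"]


@dataclass
class ProjectionModel:
    """Frozen projector: coordinate regressors + phenogroup classifier."""

    reg_dim1: XGBRegressor
    reg_dim2: XGBRegressor
    knn: KNeighborsClassifier
    k: int
    train_metrics: dict[str, float]
    edges: np.ndarray  # (E, 2, 2): segment endpoints in embedding space
    reference_coords: np.ndarray
    reference_groups: np.ndarray


def _tree_edges(model: TreeModel) -> np.ndarray:
    ii, jj = np.nonzero(np.triu(model.B))
    return np.stack([model.Y[ii], model.Y[jj]], axis=1)


def snap_to_tree(points: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Snap each point to the nearest point on any tree edge.

    Orthogonal projection onto each segment (clamped to its endpoints),
    minimized over edges.  ``points``: (M, 2); ``edges``: (E, 2, 2).
    """
    p0 = edges[:, 0]  # (E, 2)
    d = edges[:, 1] - edges[:, 0]
    len2 = np.maximum(np.sum(d**2, axis=1), 1e-300)
    # t[m, e] = clamp(<x_m - p0_e, d_e> / |d_e|^2, 0, 1)
    t = ((points[:, None, :] - p0[None, :, :]) * d[None, :, :]
         ).sum(axis=2) / len2[None, :]
    t = np.clip(t, 0.0, 1.0)
    proj = p0[None, :, :] + t[:, :, None] * d[None, :, :]  # (M, E, 2)
    dist2 = np.sum((proj - points[:, None, :]) ** 2, axis=2)
    best = np.argmin(dist2, axis=1)
    return proj[np.arange(len(points)), best]


def fit_projection(
    reference: TreeModel,
    features: np.ndarray,
    split: float = 0.75,
    k_grid: range | None = None,
    seed: int = 0,
) -> ProjectionModel:
    """Train the coordinate regressors and phenogroup classifier.

    Parameters
    ----------
    reference : fitted TreeModel with phenogroups assigned.
    features : (N, d) latent features of the reference cohort, row-aligned
        with the tree's samples.
    split : float in (0, 1)
        Train fraction of the train/validation split (default 0.75).
    k_grid : iterable of int
        Candidate neighbour counts; default ``range(1, 201)``, truncated
        with a warning when the CV folds cannot support it.
    seed : int

    Returns
    -------
    ProjectionModel with validation R^2 / MAE per dimension recorded in
    ``train_metrics``.
    """
    if not 0.0 < split < 1.0:
        raise ValueError("split must lie in (0, 1)")
    if reference.phenogroup is None:
        raise ValueError("reference tree has no phenogroups; "
                         "run merge_branches first")
    X = np.asarray(features, dtype=float)
    Z = reference.Z
    groups = reference.phenogroup
    idx_tr, idx_va = train_test_split(
        np.arange(len(X)), train_size=split, random_state=seed,
        stratify=groups,
    )

    regs = []
    metrics: dict[str, float] = {}
    for dim in (0, 1):
        reg = XGBRegressor(
            n_estimators=300, max_depth=5, learning_rate=0.1,
            subsample=0.9, colsample_bytree=0.9, random_state=seed,
            n_jobs=1, verbosity=0,
        )
        reg.fit(X[idx_tr], Z[idx_tr, dim])
        pred = reg.predict(X[idx_va])
        metrics[f"r2_dim{dim+1}"] = float(r2_score(Z[idx_va, dim], pred))
        metrics[f"mae_dim{dim+1}"] = float(
            mean_absolute_error(Z[idx_va, dim], pred)
        )
        regs.append(reg)

    # k selection: 10-fold CV on the reference coordinates
    k_grid = range(1, 201) if k_grid is None else k_grid
    counts = np.bincount(groups)
    min_class = counts[counts > 0].min()
    n_folds = 10
    max_k = int(len(idx_tr) * (n_folds - 1) / n_folds)
    if min_class < n_folds or max(k_grid) > max_k:
        k_grid = range(1, max(2, min(max(k_grid), max_k)) + 1)
        warnings.warn(
            f"k grid truncated to 1..{max(k_grid)} for the available folds"
        )
    skf = StratifiedKFold(n_splits=min(n_folds, int(min_class)) if
                          min_class < n_folds else n_folds,
                          shuffle=True, random_state=seed)
    ks = np.array(list(k_grid))
    scores = np.zeros(len(ks))
    for tr, va in skf.split(Z, groups):
        knn_all = KNeighborsClassifier(n_neighbors=int(ks.max()),
                                       weights="uniform")
        knn_all.fit(Z[tr], groups[tr])
        dists, nbrs = knn_all.kneighbors(Z[va])
        labels = groups[tr][nbrs]  # (n_va, k_max)
        for i, k in enumerate(ks):
            votes = labels[:, :k]
            pred = np.array([np.bincount(v).argmax() for v in votes])
            scores[i] += f1_score(groups[va], pred, average="macro")
    best_k = int(ks[np.argmax(scores)])
    metrics["knn_macro_f1"] = float(scores.max() / skf.get_n_splits())

    knn = KNeighborsClassifier(n_neighbors=best_k)
    knn.fit(Z, groups)
    return ProjectionModel(
        reg_dim1=regs[0], reg_dim2=regs[1], knn=knn, k=best_k,
        train_metrics=metrics, edges=_tree_edges(reference),
        reference_coords=Z.copy(), reference_groups=groups.copy(),
    )


def project_cohort(
    model: ProjectionModel, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project new samples onto the frozen tree.

    Returns
    -------
    (coords_raw, coords_snapped, phenogroup) with shapes
    (M, 2), (M, 2), (M,).  The tree is never refit.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    raw = np.column_stack([
        model.reg_dim1.predict(X), model.reg_dim2.predict(X)
    ]).astype(float)
    snapped = snap_to_tree(raw, model.edges)
    # k-NN vote; ties broken by smallest mean distance to the tied class
    dists, nbrs = model.knn.kneighbors(snapped)
    labels = model.reference_groups[nbrs]  # (M, k)
    groups = np.empty(len(snapped), dtype=labels.dtype)
    for m in range(len(snapped)):
        counts = np.bincount(labels[m])
        top = np.flatnonzero(counts == counts.max())
        if len(top) == 1:
            groups[m] = top[0]
        else:
            mean_d = [dists[m][labels[m] == c].mean() for c in top]
            groups[m] = top[int(np.argmin(mean_d))]
    return raw, snapped, groups
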