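"""Shared fixtures: synthetic fixtures are generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from phenotree.synthetic import MorphologyParams, generate_cohort
from phenotree.tree import assign_branches, fit_ddrtree, merge_branches


def make_star(seed: int, n_per: int = 200, noise: float = 0.05,
              n_arms: int = 3, dim: int = 10):
    """3-armed star in 10-D: arms along orthogonal axes, uniform length."""
    rng = np.random.default_rng(seed)
    X, lab = [], []
    for arm in range(n_arms):
        d = np.zeros(dim)
        d[arm] = 1.0
        t = rng.uniform(0, 1, n_per)
        X.append(np.outer(t, d) + rng.normal(0, noise, (n_per, dim)))
        lab += [arm] * n_per
    return np.vstack(X), np.array(lab)


@pytest.fixture(scope="session")
def star_data():
    return make_star(seed=0)


@pytest.fixture(scope="session")
def star_tree(star_data):
    """Fitted, merged tree on the canonical star instance."""
    X, _ = star_data
    model = fit_ddrtree(X, n_centroids=60, seed=0, normalize="global")
    return merge_branches(assign_branches(model), n_groups=3)


@pytest.fixture(scope="session")
def small_cohort():
    """Metadata-only cohort for statistical tests (no waveforms)."""
    _, table = generate_cohort(2000, seed=42, return_waveforms=False)
    return table


@pytest.fixture
def lbbb_params():
    return MorphologyParams(class_label="LBBB-like", qrs_duration_ms=140.0,
                            severity=0.5)
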