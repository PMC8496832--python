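"""2-D ordination of read embeddings by principal component analysis."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA


@dataclass
class Projection:
    """Top-2 principal-component coordinates of a set of embeddings."""

    coords: np.ndarray              # n x 2, centred
    variance_explained: np.ndarray  # 2 fractions, non-increasing
    component_loadings: np.ndarray  # 2 x d
    degenerate: bool = False        # second component carries no variance


def pca_project(embeddings: np.ndarray) -> Projection:
    """Project embeddings onto the top 2 principal components.

    Covariance PCA (no scaling to unit variance, the usual choice for
    embedding ordinations).  Component signs are fixed by making each
    component's largest-magnitude loading positive, so the projection is
    fully deterministic.  Rank-1 input yields a zero-variance second
    component, flagged via ``degenerate``.
    """
    X = np.asarray(embeddings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need an n x d matrix with n >= 3 and d >= 2")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(2):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            coords[:, i] *= -1
    degenerate = bool(pca.explained_variance_[1] <= 1e-12 * max(pca.explained_variance_[0], 1.0))
    if degenerate:
        warnings.warn("input is rank-deficient: second component has no variance",
                      stacklevel=2)
    return Projection(
        coords=coords,
        variance_explained=pca.explained_variance_ratio_.copy(),
        component_loadings=loadings,
        degenerate=degenerate,
    )
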