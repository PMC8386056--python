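"""Expression normalization and PCA projection to a common feature count.

Source and target cohorts generally have different sample counts, but the
downstream metric learning and fusion steps operate on per-gene feature
vectors of a shared dimension ``k`` (default 80). Genes are the PCA
observations and samples the features.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.decomposition import PCA

from .core import ExpressionMatrix

__all__ = ["standardize", "pca_project", "pca_explained_variance", "harmonize_dims"]

DEFAULT_N_FEATURES = 80


def standardize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene row (mean 0, unit sample variance, ddof=1).

    Rows with zero variance become all-zero rows with a warning. Idempotent
    on already-standardized rows.
    """
    v = x.values
    mean = v.mean(axis=1, keepdims=True)
    std = v.std(axis=1, ddof=1, keepdims=True)
    flat = (std == 0).ravel()
    if flat.any():
        genes = [g for g, f in zip(x.gene_ids, flat) if f]
        warnings.warn(
            f"{len(genes)} constant gene row(s) set to zero: "
            f"{genes[:5]}{'...' if len(genes) > 5 else ''}",
            stacklevel=2,
        )
    std = np.where(std == 0, 1.0, std)
    out = (v - mean) / std
    out[flat] = 0.0
    return ExpressionMatrix(x.gene_ids, x.sample_ids, out)


def _as_array(x) -> np.ndarray:
    return x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)


def _sign_fix(components: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Deterministic orientation: the largest-magnitude loading of each
    # component is made positive, independent of the LAPACK backend.
    for j in range(components.shape[0]):
        idx = np.argmax(np.abs(components[j]))
        if components[j, idx] < 0:
            components[j] *= -1
            scores[:, j] *= -1
    return components, scores


def pca_project(x, k: int, seed: int = 0) -> np.ndarray:
    """Project rows to their top-``k`` principal-component scores.

    Parameters
    ----------
    x : ExpressionMatrix or ndarray (n x d)
        Rows are observations (genes), columns features (samples).
    k : int
        Number of components; must satisfy ``k <= min(n, d)``.
    seed : int
        Kept for interface stability; the full SVD solver is deterministic
        and the sign convention removes backend ambiguity.

    Returns
    -------
    ndarray of shape (n, k)
    """
    v = _as_array(x)
    n, d = v.shape
    if not 1 <= k <= min(n, d):
        raise ValueError(f"k={k} must be in [1, min(n={n}, d={d})]")
    pca = PCA(n_components=k, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(v)
    _, scores = _sign_fix(pca.components_, scores)
    return scores


def pca_explained_variance(x, k: int) -> np.ndarray:
    """Explained-variance ratios of the top-``k`` components (non-increasing)."""
    v = _as_array(x)
    if not 1 <= k <= min(v.shape):
        raise ValueError("k out of range")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(v)
    return pca.explained_variance_ratio_


def harmonize_dims(
    source: ExpressionMatrix,
    target: ExpressionMatrix,
    k: int = DEFAULT_N_FEATURES,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Independently PCA-project both cohorts to ``k`` shared features.

    Both matrices must list the same genes in the same order.
    """
    if source.gene_ids != target.gene_ids:
        raise ValueError("source and target must share an identical gene order")
    return pca_project(source, k, seed), pca_project(target, k, seed)
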