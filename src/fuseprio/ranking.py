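"""Gene prioritization by network propagation on a weighted gene network.

Two propagation schemes are provided: a restart-style propagation on the
symmetrically normalized network (the method the pipeline uses) and
personalized PageRank on the column-stochastic transition matrix (the
comparison baseline). Both return :class:`~fuseprio.core.GeneRanking`
objects with strictly positive scores and deterministic tie-breaking.
"""

from __future__ import annotations

import numpy as np

from .core import GeneRanking, PathogenicLabels, WeightedNetwork

__all__ = [
    "normalize_network",
    "prince_scores",
    "prince_rank",
    "pagerank_scores",
    "pagerank_rank",
    "build_prior_from_source",
]

_SCORE_EPS = 1e-12


def normalize_network(w: WeightedNetwork) -> np.ndarray:
    """Symmetric normalization ``D^{-1/2} W D^{-1/2}``.

    Zero-degree rows/columns are left all-zero. The spectral radius of the
    result is at most 1.
    """
    deg = w.degrees
    inv_sqrt = np.zeros_like(deg)
    pos = deg > 0
    inv_sqrt[pos] = 1.0 / np.sqrt(deg[pos])
    return inv_sqrt[:, None] * w.weights * inv_sqrt[None, :]


def prince_scores(
    w: WeightedNetwork,
    prior: np.ndarray,
    alpha: float = 0.9,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    f0: np.ndarray | None = None,
) -> np.ndarray:
    """Iterate ``F <- alpha * What @ F + (1 - alpha) * Y`` to its fixed point.

    ``Y`` is the L1-normalized prior. Since the spectral radius of
    ``alpha * What`` is below 1, the fixed point ``(1 - alpha)(I - alpha
    What)^{-1} Y`` is unique and independent of the start ``f0``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    prior = np.asarray(prior, dtype=float)
    if prior.ndim != 1 or prior.shape[0] != w.n_genes:
        raise ValueError("prior length must match the network")
    if prior.min() < 0:
        raise ValueError("prior must be nonnegative")
    total = prior.sum()
    if total == 0:
        raise ValueError("prior must have at least one positive entry")
    y = prior / total
    what = normalize_network(w)
    f = y.copy() if f0 is None else np.asarray(f0, dtype=float).copy()
    for _ in range(max_iter):
        f_new = alpha * (what @ f) + (1.0 - alpha) * y
        if np.abs(f_new - f).sum() < tol:
            f = f_new
            break
        f = f_new
    return f


def prince_rank(
    w: WeightedNetwork,
    prior: np.ndarray,
    alpha: float = 0.9,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> GeneRanking:
    """Propagation ranking; scores are shifted by a tiny epsilon so every
    gene carries a strictly positive score (centrality maps to (0, inf))."""
    f = prince_scores(w, prior, alpha=alpha, tol=tol, max_iter=max_iter)
    return GeneRanking.from_scores(w.gene_ids, f + _SCORE_EPS)


def pagerank_scores(
    w: WeightedNetwork,
    damping: float = 0.85,
    personalization: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Power iteration for personalized PageRank; scores sum to 1.

    The transition matrix is column-stochastic (weights divided by column
    sums); dangling (zero-degree) nodes redistribute their mass through the
    teleport vector, which defaults to uniform.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError("damping must lie in (0, 1)")
    n = w.n_genes
    if personalization is None:
        v = np.full(n, 1.0 / n)
    else:
        v = np.asarray(personalization, dtype=float)
        if v.ndim != 1 or v.shape[0] != n:
            raise ValueError("personalization length must match the network")
        if v.min() < 0 or v.sum() == 0:
            raise ValueError("personalization must be nonnegative with positive sum")
        v = v / v.sum()
    col = w.weights.sum(axis=0)
    dangling = col == 0
    T = np.zeros_like(w.weights)
    nz = ~dangling
    T[:, nz] = w.weights[:, nz] / col[nz]
    p = v.copy()
    for _ in range(max_iter):
        dangling_mass = p[dangling].sum()
        p_new = damping * (T @ p + dangling_mass * v) + (1.0 - damping) * v
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            break
        p = p_new
    return p


def pagerank_rank(
    w: WeightedNetwork,
    damping: float = 0.85,
    personalization: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> GeneRanking:
    p = pagerank_scores(w, damping=damping, personalization=personalization, tol=tol, max_iter=max_iter)
    return GeneRanking.from_scores(w.gene_ids, p + _SCORE_EPS)


def build_prior_from_source(labels: PathogenicLabels) -> np.ndarray:
    """L1-normalized indicator of source-pathogenic genes.

    The target cohort carries no labels of its own; because both cohorts
    share the gene universe, the source label vector is the natural
    propagation seed.
    """
    y = np.asarray(labels.labels, dtype=float)
    total = y.sum()
    if total == 0:
        raise ValueError("no pathogenic genes in the source labels")
    return y / total
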