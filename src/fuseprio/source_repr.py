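"""Supervised low-dimensional representation of source-cohort genes.

A linear map ``H`` (k x r) is learned by the large-margin nearest neighbor
(LMNN) criterion on the binary pathogenic labels: same-class target
neighbors are pulled together while differently labeled "impostors" are
pushed outside a unit margin. The learned representation is ``A = X @ H``,
which reproduces the projected expression exactly (zero residual) while
separating the two classes.

The solver is plain gradient descent with a backtracking line search on the
exact hinge loss; no semidefinite programming. Target neighbors are fixed
at initialization and the active impostor set is refreshed periodically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .core import PathogenicLabels

__all__ = ["SourceRepresentation", "fit_lmnn", "class_separation_score"]

_EPS_GUARD = 1e-12


@dataclass
class SourceRepresentation:
    """Learned embedding ``A = X @ H`` of the source genes."""

    A: np.ndarray
    H: np.ndarray
    r: int
    loss_trace: list[float] = field(default_factory=list)


def _pairwise_sq(P: np.ndarray) -> np.ndarray:
    d = squareform(pdist(P, metric="sqeuclidean"))
    return d


def _target_neighbors(X: np.ndarray, y: np.ndarray, n_neighbors: int) -> np.ndarray:
    """n x n_neighbors index array of same-class nearest neighbors (input space)."""
    d = _pairwise_sq(X)
    np.fill_diagonal(d, np.inf)
    out = np.empty((X.shape[0], n_neighbors), dtype=int)
    for i in range(X.shape[0]):
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        order = same[np.argsort(d[i, same], kind="stable")]
        out[i] = order[:n_neighbors]
    return out


def _active_triples(
    d2: np.ndarray, y: np.ndarray, neighbors: np.ndarray
) -> list[tuple[int, int, np.ndarray]]:
    """Hinge-active (i, j, impostors) triples under current distances."""
    triples = []
    for i in range(d2.shape[0]):
        diff = np.flatnonzero(y != y[i])
        for j in neighbors[i]:
            margin = 1.0 + d2[i, j]
            imp = diff[d2[i, diff] < margin]
            if imp.size:
                triples.append((i, int(j), imp))
    return triples


def _lmnn_loss(
    d2: np.ndarray,
    y: np.ndarray,
    neighbors: np.ndarray,
    mu: float,
) -> float:
    pull = 0.0
    push = 0.0
    for i in range(d2.shape[0]):
        diff = np.flatnonzero(y != y[i])
        for j in neighbors[i]:
            pull += d2[i, j]
            slack = 1.0 + d2[i, j] - d2[i, diff]
            push += slack[slack > 0].sum()
    return (1.0 - mu) * pull + mu * push


def _lmnn_grad_coeffs(
    n: int,
    neighbors: np.ndarray,
    triples: list[tuple[int, int, np.ndarray]],
    mu: float,
) -> np.ndarray:
    """Pair-coefficient matrix G so that grad = 2 X' Λ(G) X H."""
    G = np.zeros((n, n))
    for i in range(n):
        G[i, neighbors[i]] += 1.0 - mu
    for i, j, imp in triples:
        G[i, j] += mu * imp.size
        G[i, imp] -= mu
    return G


def _coeff_laplacian(G: np.ndarray) -> np.ndarray:
    # sum_ij g_ij (x_i - x_j)'(x_i - x_j) = X' Λ X with this Λ
    return np.diag(G.sum(axis=1)) + np.diag(G.sum(axis=0)) - G - G.T


def _pca_init(X: np.ndarray, r: int) -> np.ndarray:
    Xc = X - X.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    H = vt[:r].T
    for j in range(r):
        idx = np.argmax(np.abs(H[:, j]))
        if H[idx, j] < 0:
            H[:, j] *= -1
    return H


def fit_lmnn(
    source_feats: np.ndarray,
    labels: PathogenicLabels,
    r: int | None = None,
    n_neighbors: int = 3,
    margin_weight: float = 0.5,
    max_iter: int = 100,
    seed: int = 0,
    init: str = "pca",
    impostor_refresh: int = 10,
    step_init: float = 1e-3,
    tol: float = 1e-7,
) -> SourceRepresentation:
    """Learn ``H`` by gradient-descent LMNN; return ``A = X @ H``.

    Parameters
    ----------
    source_feats : ndarray (n x k)
        Per-gene feature vectors of the source cohort.
    labels : PathogenicLabels
        Binary labels over the same genes; both classes required and each
        class must exceed ``n_neighbors`` members.
    r : int, optional
        Embedding dimension (default ``k``).
    margin_weight : float in (0, 1)
        Trade-off ``mu`` between pull (1 - mu) and push (mu) terms.
    init : {"pca", "identity"}
        Deterministic initialization of ``H``.

    Notes
    -----
    The loss is non-increasing across accepted steps by construction
    (simple-decrease backtracking on the exact loss). ``seed`` is accepted
    for interface stability; the procedure is fully deterministic.
    """
    X = np.asarray(source_feats, dtype=float)
    n, k = X.shape
    y = np.asarray(labels.labels)
    if y.shape[0] != n:
        raise ValueError("labels not aligned to features")
    if y.min() == y.max():
        raise ValueError("LMNN requires both classes present")
    class_sizes = [int((y == c).sum()) for c in (0, 1)]
    if min(class_sizes) <= n_neighbors:
        raise ValueError(
            f"smallest class has {min(class_sizes)} members <= n_neighbors="
            f"{n_neighbors}; use a smaller n_neighbors"
        )
    if not 0.0 < margin_weight < 1.0:
        raise ValueError("margin_weight must lie in (0, 1)")
    if r is None:
        r = k
    if not 1 <= r <= k:
        raise ValueError(f"r={r} must be in [1, k={k}]")

    if init == "identity":
        H = np.eye(k, r)
    elif init == "pca":
        H = _pca_init(X, r)
    else:
        raise ValueError(f"unknown init {init!r}")

    neighbors = _target_neighbors(X, y, n_neighbors)
    mu = margin_weight

    def loss_at(H_):
        return _lmnn_loss(_pairwise_sq(X @ H_), y, neighbors, mu)

    loss = loss_at(H)
    trace = [loss]
    step = step_init
    triples = _active_triples(_pairwise_sq(X @ H), y, neighbors)
    for it in range(max_iter):
        if it % impostor_refresh == 0:
            triples = _active_triples(_pairwise_sq(X @ H), y, neighbors)
        G = _lmnn_grad_coeffs(n, neighbors, triples, mu)
        grad = 2.0 * X.T @ (_coeff_laplacian(G) @ (X @ H))
        gnorm = np.linalg.norm(grad)
        if gnorm == 0:
            break
        # backtracking: accept only strict non-increase of the exact loss
        accepted = False
        s = step
        while s >= 1e-12:
            H_new = H - s * grad
            loss_new = loss_at(H_new)
            if loss_new <= loss:
                accepted = True
                break
            s *= 0.5
        if not accepted:
            # stale active set may block progress; refresh once and bail if still stuck
            triples = _active_triples(_pairwise_sq(X @ H), y, neighbors)
            G = _lmnn_grad_coeffs(n, neighbors, triples, mu)
            grad = 2.0 * X.T @ (_coeff_laplacian(G) @ (X @ H))
            s = step
            while s >= 1e-12:
                H_new = H - s * grad
                loss_new = loss_at(H_new)
                if loss_new <= loss:
                    accepted = True
                    break
                s *= 0.5
            if not accepted:
                break
        improvement = loss - loss_new
        H, loss = H_new, loss_new
        trace.append(loss)
        step = min(s * 2.0, 1.0)
        if improvement <= tol * max(abs(loss), 1.0):
            break

    return SourceRepresentation(A=X @ H, H=H, r=r, loss_trace=trace)


def class_separation_score(A: np.ndarray, labels: PathogenicLabels, eps: float = _EPS_GUARD) -> float:
    """(mean inter-class pairwise distance) / (mean intra-class pairwise distance).

    Pair means run over distinct ordered pairs. A near-zero intra-class mean
    is guarded: the score is capped at ``1/eps``. If one class is a
    singleton, the intra-class mean falls back to the other class with a
    warning.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(labels.labels)
    if A.shape[0] != y.shape[0]:
        raise ValueError("labels not aligned to embedding rows")
    if y.min() == y.max():
        raise ValueError("both classes required")
    d = squareform(pdist(A))
    same = y[:, None] == y[None, :]
    np.fill_diagonal(same, False)
    diff = y[:, None] != y[None, :]
    for c in (0, 1):
        if (y == c).sum() == 1:
            warnings.warn(
                f"class {c} is a singleton; intra-class mean uses the other class only",
                stacklevel=2,
            )
            same &= ~np.outer(y == c, y == c)
    inter = d[diff].mean()
    intra = d[same].mean()
    if intra < eps:
        return 1.0 / eps
    return float(inter / intra)
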