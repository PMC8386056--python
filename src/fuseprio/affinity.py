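"""Cross-cohort gene affinity matrix.

Entry ``s[i, j]`` is the absolute Pearson correlation between target gene
``i``'s feature vector and source gene ``j``'s feature vector: rows index
the target cohort, columns the source cohort. The matrix is deliberately
NOT symmetrized — it is a bipartite target-by-source similarity even though
both sides range over the same gene universe — so the row-sum and
column-sum degree diagonals are kept separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["AffinityMatrix", "build_affinity", "sparsify_affinity"]


@dataclass
class AffinityMatrix:
    """Nonnegative n x n affinity with cached row/column degree vectors."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("affinity must be a square matrix")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("affinity entries must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def row_degree(self) -> np.ndarray:
        """Row sums (target-side degrees)."""
        return self.values.sum(axis=1)

    @property
    def col_degree(self) -> np.ndarray:
        """Column sums (source-side degrees)."""
        return self.values.sum(axis=0)


def _row_zscores(feats: np.ndarray, side: str) -> tuple[np.ndarray, np.ndarray]:
    mean = feats.mean(axis=1, keepdims=True)
    centered = feats - mean
    norm = np.linalg.norm(centered, axis=1, keepdims=True)
    flat = (norm.ravel() == 0)
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance {side} row(s); their affinities set to 0",
            stacklevel=3,
        )
    norm = np.where(norm == 0, 1.0, norm)
    return centered / norm, flat


def build_affinity(target_feats: np.ndarray, source_feats: np.ndarray) -> AffinityMatrix:
    """|Pearson| affinity between target rows (axis 0) and source rows (axis 1).

    Both inputs must be n x k with the same gene order and ``k >= 3``.
    Zero-variance rows give zero affinity with a warning.
    """
    t = np.asarray(target_feats, dtype=float)
    s = np.asarray(source_feats, dtype=float)
    if t.shape != s.shape:
        raise ValueError(f"feature shapes differ: {t.shape} vs {s.shape}")
    if t.ndim != 2 or t.shape[1] < 3:
        raise ValueError("need n x k features with k >= 3")
    tz, t_flat = _row_zscores(t, "target")
    sz, s_flat = _row_zscores(s, "source")
    corr = np.abs(tz @ sz.T)
    corr[t_flat, :] = 0.0
    corr[:, s_flat] = 0.0
    return AffinityMatrix(np.clip(corr, 0.0, 1.0))


def sparsify_affinity(s: AffinityMatrix, top_m: int) -> AffinityMatrix:
    """Keep the ``top_m`` largest entries of each row, zero the rest.

    Ties at the cutoff are resolved by keeping the lowest column index
    (stable sort), so the result is deterministic.
    """
    n = s.n
    if not 1 <= top_m <= n:
        raise ValueError(f"top_m={top_m} must be in [1, n={n}]")
    if top_m == n:
        return AffinityMatrix(s.values.copy())
    out = np.zeros_like(s.values)
    for i in range(n):
        keep = np.argsort(-s.values[i], kind="stable")[:top_m]
        out[i, keep] = s.values[i, keep]
    return AffinityMatrix(out)
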