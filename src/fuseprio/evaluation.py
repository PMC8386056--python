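"""Evaluation procedures: reference-edge overlap, top-k accuracy, uniquely
ranked genes, and the co-expression baseline network."""

from __future__ import annotations

import warnings

import numpy as np

from .core import ExpressionMatrix, GeneRanking, PathogenicLabels, WeightedNetwork

__all__ = [
    "edge_overlap_fraction",
    "overlap_sweep",
    "topk_accuracy",
    "uniquely_ranked",
    "coexpression_network",
]

#: Fig.-2-style threshold multipliers: 1.2 to 2.0 in steps of 0.02.
DEFAULT_ALPHA_SWEEP = tuple(np.round(np.arange(1.2, 2.0 + 1e-9, 0.02), 2))


def _shared_universe(net: WeightedNetwork, reference: WeightedNetwork):
    if net.gene_ids == reference.gene_ids:
        return net.weights, reference.weights
    ref_set = set(reference.gene_ids)
    shared = [g for g in net.gene_ids if g in ref_set]
    if not shared:
        raise ValueError("networks share no genes")
    warnings.warn(
        f"networks differ in gene universe; evaluating on the {len(shared)}-gene intersection",
        stacklevel=3,
    )
    ni = {g: i for i, g in enumerate(net.gene_ids)}
    ri = {g: i for i, g in enumerate(reference.gene_ids)}
    nidx = [ni[g] for g in shared]
    ridx = [ri[g] for g in shared]
    return net.weights[np.ix_(nidx, nidx)], reference.weights[np.ix_(ridx, ridx)]


def edge_overlap_fraction(
    net: WeightedNetwork, reference: WeightedNetwork, alpha_mult: float
) -> float:
    """Fraction of thresholded edges of ``net`` present in ``reference``.

    Edges kept are the unordered pairs whose weight exceeds ``alpha_mult``
    times the mean positive off-diagonal weight of ``net``. The reference is
    treated as unweighted presence/absence. Returns 0 with a warning when no
    edge passes the threshold.
    """
    if alpha_mult < 0:
        raise ValueError("alpha_mult must be >= 0")
    w, ref = _shared_universe(net, reference)
    iu = np.triu_indices(w.shape[0], k=1)
    wv = w[iu]
    pos = wv[wv > 0]
    if pos.size == 0:
        warnings.warn("network has no positive edges", stacklevel=2)
        return 0.0
    threshold = alpha_mult * pos.mean()
    selected = wv > threshold
    n_sel = int(selected.sum())
    if n_sel == 0:
        warnings.warn(f"no edge exceeds threshold {threshold:.4g}", stacklevel=2)
        return 0.0
    hits = int((ref[iu][selected] > 0).sum())
    return hits / n_sel


def overlap_sweep(
    net: WeightedNetwork,
    reference: WeightedNetwork,
    alpha_mults=DEFAULT_ALPHA_SWEEP,
) -> list[tuple[float, float]]:
    """Overlap fraction at each threshold multiplier."""
    return [(float(a), edge_overlap_fraction(net, reference, a)) for a in alpha_mults]


def topk_accuracy(r: GeneRanking, truth: PathogenicLabels, k: int) -> float:
    """|top-k genes that are truth-positive| / k."""
    if not 1 <= k <= len(r):
        raise ValueError(f"k={k} must be in [1, {len(r)}]")
    positives = set(truth.positives())
    return sum(1 for g in r.top(k) if g in positives) / k


def uniquely_ranked(
    r_a: GeneRanking, r_b: GeneRanking, truth: PathogenicLabels, k: int
) -> tuple[int, int]:
    """Truth-positive genes in one ranking's top-k but not the other's.

    Returns ``(count_a_only, count_b_only)``.
    """
    positives = set(truth.positives())
    top_a = set(r_a.top(k))
    top_b = set(r_b.top(k))
    a_only = len((top_a - top_b) & positives)
    b_only = len((top_b - top_a) & positives)
    return a_only, b_only


def coexpression_network(target: ExpressionMatrix) -> WeightedNetwork:
    """Baseline network: ``w_ij = |Pearson(x_i, x_j)|`` within one cohort.

    Zero-variance genes get zero weights; the diagonal is zero.
    """
    v = target.values
    centered = v - v.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1, keepdims=True)
    flat = (norm.ravel() == 0)
    norm = np.where(norm == 0, 1.0, norm)
    z = centered / norm
    w = np.abs(z @ z.T)
    w[flat, :] = 0.0
    w[:, flat] = 0.0
    np.clip(w, 0.0, 1.0, out=w)
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(target.gene_ids, w)
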