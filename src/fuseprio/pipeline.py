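"""End-to-end pipeline: expression cohorts + source labels -> fused network
and gene ranking.

Steps: align gene universes, row-standardize, PCA-harmonize feature
dimensions, build the cross-cohort affinity, learn the supervised source
representation, fit the fusion network, and propagate the source-label
prior on it.

The affinity is computed on the standardized raw sample space when the two
cohorts happen to have the same sample count (paired coordinates exist),
and in the common PCA space otherwise. This convention is ours — the
underlying method leaves the point ambiguous — and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from scipy.spatial.distance import pdist

from .affinity import AffinityMatrix, build_affinity
from .core import ExpressionMatrix, GeneRanking, PathogenicLabels, align_gene_universe
from .fusion import FusionModel, fit as fit_fusion
from .preprocess import DEFAULT_N_FEATURES, harmonize_dims, standardize
from .ranking import build_prior_from_source, pagerank_rank, prince_rank
from .source_repr import SourceRepresentation, fit_lmnn

__all__ = ["PipelineResult", "prioritize"]


@dataclass
class PipelineResult:
    """All intermediate artifacts of one pipeline run."""

    source: ExpressionMatrix
    target: ExpressionMatrix
    labels: PathogenicLabels
    source_feats: np.ndarray
    target_feats: np.ndarray
    affinity: AffinityMatrix
    representation: SourceRepresentation
    fusion: FusionModel
    ranking: GeneRanking


def prioritize(
    source: ExpressionMatrix,
    target: ExpressionMatrix,
    labels: PathogenicLabels,
    n_features: int = DEFAULT_N_FEATURES,
    lam: float = 1.0,
    r: int | None = None,
    n_neighbors: int = 3,
    margin_weight: float = 0.5,
    lmnn_max_iter: int = 100,
    fusion_max_iter: int = 200,
    fusion_tol: float = 1e-5,
    method: str = "prince",
    alpha: float = 0.9,
    damping: float = 0.85,
    affinity_space: str = "auto",
    representation_scale: float = 300.0,
    seed: int = 0,
) -> PipelineResult:
    """Run the full prioritization pipeline.

    Parameters
    ----------
    n_features : int
        Requested common feature count (default 80); capped at
        ``min(d_source, d_target, n_genes)``.
    lam : float
        Fusion penalty weight (default 1).
    method : {"prince", "pagerank"}
        Propagation scheme used for the final ranking.
    affinity_space : {"auto", "raw", "pca"}
        Where the cross-cohort Pearson affinity is computed. "auto" uses the
        standardized raw sample space when sample counts match, else PCA.
    representation_scale : float
        The source representation ``A`` is rescaled so that its mean pairwise
        squared row distance equals ``representation_scale * lam`` before the
        fusion fit. The closed-form weight rule maps squared distances
        through ``(lam / (d^2 + lam))^2`` and saturates at 1 when distances
        are small relative to ``lam``; anchoring the scale keeps the learned
        weights spread over (0, 1). Set to 0 to disable.
    """
    source, target, labels = align_gene_universe(source, target, labels)
    source_std = standardize(source)
    target_std = standardize(target)

    k = min(n_features, source.n_samples, target.n_samples, source.n_genes)
    source_feats, target_feats = harmonize_dims(source_std, target_std, k=k, seed=seed)

    if affinity_space == "auto":
        affinity_space = "raw" if source.n_samples == target.n_samples else "pca"
    if affinity_space == "raw":
        if source.n_samples != target.n_samples:
            raise ValueError("raw affinity space requires equal sample counts")
        S = build_affinity(target_std.values, source_std.values)
    elif affinity_space == "pca":
        S = build_affinity(target_feats, source_feats)
    else:
        raise ValueError(f"unknown affinity_space {affinity_space!r}")

    rep = fit_lmnn(
        source_feats,
        labels,
        r=r,
        n_neighbors=n_neighbors,
        margin_weight=margin_weight,
        max_iter=lmnn_max_iter,
        seed=seed,
    )
    A = rep.A
    if representation_scale > 0:
        msd = float(np.mean(pdist(A, metric="sqeuclidean")))
        if msd > 0:
            A = A * np.sqrt(representation_scale * lam / msd)
    model = fit_fusion(
        target_feats,
        S,
        A,
        lam=lam,
        max_iter=fusion_max_iter,
        tol=fusion_tol,
        seed=seed,
        gene_ids=source.gene_ids,
    )
    prior = build_prior_from_source(labels)
    if method == "prince":
        ranking = prince_rank(model.network, prior, alpha=alpha)
    elif method == "pagerank":
        ranking = pagerank_rank(model.network, damping=damping, personalization=prior)
    else:
        raise ValueError(f"unknown ranking method {method!r}")

    return PipelineResult(
        source=source,
        target=target,
        labels=labels,
        source_feats=source_feats,
        target_feats=target_feats,
        affinity=S,
        representation=rep,
        fusion=model,
        ranking=ranking,
    )
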