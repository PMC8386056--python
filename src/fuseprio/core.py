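"""Core domain types and plain-text I/O.

The package works on four value types:

* :class:`ExpressionMatrix` — genes x samples real matrix with identifiers.
* :class:`PathogenicLabels` — binary per-gene disease labels.
* :class:`WeightedNetwork` — symmetric nonnegative gene-gene network with
  derived degree and Laplacian matrices.
* :class:`GeneRanking` — genes ordered by a strictly positive score.

All file formats are plain TSV / line-oriented text so fixtures survive
text-only round-trips.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PathogenicLabels",
    "WeightedNetwork",
    "GeneRanking",
    "read_expression",
    "write_expression",
    "read_gene_list",
    "write_gene_list",
    "labels_from_gene_list",
    "read_network",
    "write_network",
    "read_ranking",
    "write_ranking",
    "align_gene_universe",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes-by-samples expression matrix.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers, unique, order-preserving.
    sample_ids : list of str
        Column identifiers, unique.
    values : ndarray of shape (n_genes, n_samples)
        Real, finite expression values (e.g. log-FPKM).

    Notes
    -----
    At least 2 genes and 3 samples are required: downstream Pearson
    correlations over samples are degenerate with fewer than 3 points.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, d = self.values.shape
        if n != len(self.gene_ids) or d != len(self.sample_ids):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if n < 2:
            raise ValueError(f"need at least 2 genes, got {n}")
        if d < 3:
            raise ValueError(f"need at least 3 samples, got {d}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NaN/inf)")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def restrict(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``gene_ids`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.sample_ids, self.values[rows])


@dataclass
class PathogenicLabels:
    """Binary pathogenic indicator aligned to a gene universe.

    ``labels[i] == 1`` marks gene ``gene_ids[i]`` as pathogenic. Single-class
    label vectors are tolerated with a warning (propagation priors accept
    them) but supervised metric learning rejects them at fit time.
    """

    gene_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        _check_unique(self.gene_ids, "gene")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.shape[0] != len(self.gene_ids):
            raise ValueError("labels must be a 1-D vector aligned to gene_ids")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        if self.labels.size == 0:
            raise ValueError("labels must be non-empty")
        if self.labels.min() == self.labels.max():
            warnings.warn(
                "label vector contains a single class; metric learning will "
                "not be applicable",
                stacklevel=2,
            )

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def positives(self) -> list[str]:
        return [g for g, y in zip(self.gene_ids, self.labels) if y == 1]

    def restrict(self, gene_ids: Sequence[str]) -> "PathogenicLabels":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return PathogenicLabels(list(gene_ids), self.labels[rows])


@dataclass
class WeightedNetwork:
    """Undirected weighted gene network.

    The weight matrix is validated symmetric and nonnegative; the diagonal is
    forced to zero (self-similarity is never used and a unit self-loop would
    distort degree-based propagation).
    """

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        _check_unique(self.gene_ids, "gene")
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if w.shape[0] != len(self.gene_ids):
            raise ValueError("weights shape inconsistent with gene_ids")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if not np.allclose(w, w.T, atol=1e-8):
            raise ValueError("weights must be symmetric")
        w = (w + w.T) / 2.0
        if w.min() < -1e-12:
            raise ValueError("weights must be nonnegative")
        np.clip(w, 0.0, None, out=w)
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Per-node degree ``d_i = sum_j w_ij``."""
        return self.weights.sum(axis=1)

    @property
    def degree_matrix(self) -> np.ndarray:
        return np.diag(self.degrees)

    @property
    def laplacian(self) -> np.ndarray:
        """Combinatorial Laplacian ``D - W`` (rows sum to zero, PSD)."""
        return self.degree_matrix - self.weights


@dataclass
class GeneRanking:
    """Genes ordered by strictly positive score, descending.

    Ties are broken by lexicographic gene identifier so that rankings are
    deterministic across runs and platforms.
    """

    entries: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([g for g, _ in self.entries], "gene")
        for g, s in self.entries:
            if not (s > 0 and np.isfinite(s)):
                raise ValueError(f"score for {g!r} must be finite and > 0, got {s}")
        ordered = sorted(self.entries, key=lambda e: (-e[1], e[0]))
        if [g for g, _ in ordered] != [g for g, _ in self.entries]:
            raise ValueError("entries must be sorted by descending score, ties by gene_id")

    @classmethod
    def from_scores(cls, gene_ids: Sequence[str], scores: np.ndarray) -> "GeneRanking":
        """Build a ranking from parallel id/score arrays (sorts internally)."""
        scores = np.asarray(scores, dtype=float)
        pairs = sorted(zip(gene_ids, scores), key=lambda e: (-e[1], e[0]))
        return cls([(g, float(s)) for g, s in pairs])

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries])

    def top(self, k: int) -> list[str]:
        return self.gene_ids[:k]

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(path) -> ExpressionMatrix:
    """Read an expression TSV (header = sample IDs, first column = gene IDs).

    Rows with empty cells are dropped with a warning; any other non-numeric
    cell is a hard error naming the offending gene and sample. Duplicated
    gene or sample identifiers are hard errors.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    _check_unique(sample_ids, "sample")

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    gene_ids = [str(g) for g in df.index]
    _check_unique(gene_ids, "gene")

    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna().to_numpy()
    empty = df.eq("").to_numpy()
    nonnum = bad & ~empty
    if nonnum.any():
        i, j = np.argwhere(nonnum)[0]
        raise ValueError(
            f"non-numeric cell {df.iat[i, j]!r} at gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    drop = empty.any(axis=1)
    if drop.any():
        dropped = [g for g, d in zip(gene_ids, drop) if d]
        warnings.warn(
            f"dropping {len(dropped)} gene(s) with missing values: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
        numeric = numeric.loc[~drop]
        gene_ids = [g for g, d in zip(gene_ids, drop) if not d]
    return ExpressionMatrix(gene_ids, sample_ids, numeric.to_numpy(dtype=float))


def write_expression(x: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(x.values, index=x.gene_ids, columns=x.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_gene_list(path) -> list[str]:
    """Read a one-ID-per-line gene list; ``#`` starts a comment."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def write_gene_list(gene_ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in gene_ids:
            fh.write(f"{g}\n")


def labels_from_gene_list(positives: Iterable[str], universe: Sequence[str]) -> PathogenicLabels:
    """Binary labels over ``universe`` with 1 at each ID in ``positives``.

    IDs absent from the universe are ignored with a warning.
    """
    pos = set(positives)
    missing = pos - set(universe)
    if missing:
        warnings.warn(
            f"{len(missing)} listed gene(s) not in the expression universe; ignored",
            stacklevel=2,
        )
    labels = np.array([1 if g in pos else 0 for g in universe], dtype=int)
    return PathogenicLabels(list(universe), labels)


def read_network(path, gene_ids: Sequence[str] | None = None) -> WeightedNetwork:
    """Read a 3-column (gene_a, gene_b, weight) undirected edge-list TSV.

    If ``gene_ids`` is None the universe is the edge endpoints in order of
    first appearance; otherwise edges outside ``gene_ids`` raise an error.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) != ["gene_a", "gene_b", "weight"]:
        raise ValueError("network TSV must have columns gene_a, gene_b, weight")
    if gene_ids is None:
        seen: dict[str, None] = {}
        for a, b in zip(df["gene_a"], df["gene_b"]):
            seen.setdefault(str(a), None)
            seen.setdefault(str(b), None)
        gene_ids = list(seen)
    index = {g: i for i, g in enumerate(gene_ids)}
    n = len(gene_ids)
    w = np.zeros((n, n))
    for a, b, wt in zip(df["gene_a"], df["gene_b"], df["weight"]):
        a, b = str(a), str(b)
        if a not in index or b not in index:
            raise ValueError(f"edge ({a}, {b}) outside the provided gene universe")
        i, j = index[a], index[b]
        w[i, j] = wt
        w[j, i] = wt
    return WeightedNetwork(list(gene_ids), w)


def write_network(net: WeightedNetwork, path) -> None:
    """Write positive-weight edges, one unordered pair per line."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        n = net.n_genes
        for i in range(n):
            for j in range(i + 1, n):
                if net.weights[i, j] > 0:
                    fh.write(f"{net.gene_ids[i]}\t{net.gene_ids[j]}\t{net.weights[i, j]:.17g}\n")


def write_ranking(r: GeneRanking, path) -> None:
    """Write a ranking as TSV with columns rank, gene_id, score (rank from 1)."""
    with open(path, "w") as fh:
        fh.write("rank\tgene_id\tscore\n")
        for rank, (g, s) in enumerate(r.entries, start=1):
            fh.write(f"{rank}\t{g}\t{s:.17g}\n")


def read_ranking(path) -> GeneRanking:
    df = pd.read_csv(path, sep="\t")
    return GeneRanking([(str(g), float(s)) for g, s in zip(df["gene_id"], df["score"])])


def align_gene_universe(
    source: ExpressionMatrix,
    target: ExpressionMatrix,
    labels: PathogenicLabels,
) -> tuple[ExpressionMatrix, ExpressionMatrix, PathogenicLabels]:
    """Restrict both matrices and the labels to the shared gene universe.

    The intersection keeps the source's row order. Counts of dropped genes
    are logged. Idempotent; an empty intersection is a hard error.
    """
    if labels.gene_ids != source.gene_ids:
        raise ValueError("labels must be aligned to the source gene universe")
    target_set = set(target.gene_ids)
    shared = [g for g in source.gene_ids if g in target_set]
    if not shared:
        raise ValueError("source and target share no genes")
    n_src_drop = source.n_genes - len(shared)
    n_tgt_drop = target.n_genes - len(shared)
    if n_src_drop or n_tgt_drop:
        logger.info(
            "gene universe intersection: kept %d, dropped %d from source, %d from target",
            len(shared), n_src_drop, n_tgt_drop,
        )
    return source.restrict(shared), target.restrict(shared), labels.restrict(shared)
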