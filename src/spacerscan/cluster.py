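"""Gene x spacer-length occurrence matrices and K-means/silhouette clustering.

Genes carrying a motif pair are represented by their per-spacer hit counts
(rows: genes, columns: spacer lengths 0..30 or a subset). Spacer columns
that are zero across all genes are dropped as uninformative before
clustering. K is chosen by maximizing the mean silhouette score over a
candidate range, with a smallest-K tie-break; the full silhouette curve is
reported so a human can override the automatic pick.

No feature scaling is applied by default (counts are on a common scale);
``standardize=True`` and ``binary=True`` expose the obvious variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import DegenerateInputError, ReferenceLookupError
from .likelihood import MotifGeneIndex

# mean silhouette below this suggests no real cluster structure
LOW_SILHOUETTE = 0.25


@dataclass
class GeneSpacerMatrix:
    """Nonnegative integer counts, genes as rows, spacer lengths as columns."""

    data: pd.DataFrame  # index: gene ids, columns: int spacer lengths

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("duplicate gene or spacer labels")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def spacer_lens(self) -> list[int]:
        return [int(c) for c in self.data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class ClusteringResult:
    k: int
    assignments: dict[str, int]
    silhouette_by_k: dict[int, float]
    seed: int
    low_silhouette: bool = False
    inertia: float = field(default=float("nan"))


def build_matrix(index: MotifGeneIndex, gene_ids: list[str]) -> GeneSpacerMatrix:
    """Counts of pair hits per gene per spacer length.

    Genes without hits get all-zero rows; ids outside the index universe
    raise :class:`ReferenceLookupError`.
    """
    if not gene_ids:
        raise ValueError("gene_ids is empty")
    unknown = set(gene_ids) - set(index.universe)
    if unknown:
        raise ReferenceLookupError(f"unknown gene ids: {sorted(unknown)[:5]}")
    cols = list(index.spacer_range)
    rows = []
    for g in gene_ids:
        per_n = index.counts.get(g, {})
        rows.append([per_n.get(n, 0) for n in cols])
    df = pd.DataFrame(rows, index=list(gene_ids), columns=cols, dtype=int)
    return GeneSpacerMatrix(df)


def drop_zero_spacers(matrix: GeneSpacerMatrix) -> GeneSpacerMatrix:
    """Remove spacer columns that are zero across all genes."""
    keep = matrix.data.columns[(matrix.data != 0).any(axis=0)]
    if len(keep) == 0:
        raise DegenerateInputError("every spacer column is all-zero")
    return GeneSpacerMatrix(matrix.data[keep].copy())


def _features(matrix: GeneSpacerMatrix, standardize: bool, binary: bool) -> np.ndarray:
    X = matrix.data.to_numpy(dtype=float)
    if binary:
        X = (X > 0).astype(float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return X


def kmeans_cluster(
    matrix: GeneSpacerMatrix,
    k: int,
    seed: int,
    standardize: bool = False,
    binary: bool = False,
) -> ClusteringResult:
    """Euclidean K-means, deterministic given (matrix, k, seed)."""
    n_rows = matrix.shape[0]
    if k < 2 or k > n_rows:
        raise ValueError(f"require 2 <= k <= {n_rows}, got {k}")
    X = _features(matrix, standardize, binary)
    if np.all(X == X[0]):
        raise DegenerateInputError("all rows identical; nothing to cluster")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    if k == n_rows:
        # every row a singleton: silhouette undefined, taken as 0 by convention
        sil = 0.0
    else:
        sil = float(silhouette_score(X, labels))
    return ClusteringResult(
        k=k,
        assignments=dict(zip(matrix.gene_ids, (int(l) for l in labels))),
        silhouette_by_k={k: sil},
        seed=seed,
        low_silhouette=sil < LOW_SILHOUETTE,
        inertia=float(km.inertia_),
    )


def select_k(
    matrix: GeneSpacerMatrix,
    k_range,
    seed: int,
    standardize: bool = False,
    binary: bool = False,
) -> ClusteringResult:
    """Fit K-means over ``k_range`` and keep the silhouette-maximizing K.

    Ties go to the smallest K. ``low_silhouette`` is set when even the best
    mean silhouette is below ``LOW_SILHOUETTE``, signalling a flat curve /
    single-blob situation where the automatic pick should be reviewed.
    """
    ks = sorted(set(int(k) for k in k_range))
    n_rows = matrix.shape[0]
    if not ks:
        raise ValueError("empty k_range")
    if ks[0] < 2 or ks[-1] > n_rows - 1:
        raise ValueError(f"k_range must lie within [2, {n_rows - 1}]")
    fits = {k: kmeans_cluster(matrix, k, seed, standardize, binary) for k in ks}
    curve = {k: fits[k].silhouette_by_k[k] for k in ks}
    best_k = max(ks, key=lambda k: (curve[k], -k))
    best = fits[best_k]
    return ClusteringResult(
        k=best_k,
        assignments=best.assignments,
        silhouette_by_k=curve,
        seed=seed,
        low_silhouette=curve[best_k] < LOW_SILHOUETTE,
        inertia=best.inertia,
    )


def write_matrix_tsv(matrix: GeneSpacerMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix_tsv(path) -> GeneSpacerMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df.index.name = None
    df.columns = [int(c) for c in df.columns]
    return GeneSpacerMatrix(df.astype(int))


def write_assignments_tsv(result: ClusteringResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcluster\n")
        for g, c in result.assignments.items():
            fh.write(f"{g}\t{c}\n")


def write_silhouette_tsv(result: ClusteringResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("k\tmean_silhouette\n")
        for k in sorted(result.silhouette_by_k):
            fh.write(f"{k}\t{result.silhouette_by_k[k]:.6g}\n")
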