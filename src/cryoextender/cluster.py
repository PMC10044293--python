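"""UPGMA clustering of bulls on their mean PLS scores.

Bulls are represented by the per-bull average of the first three latent
scores (t1, t2, t3); pairwise Euclidean distances feed average-linkage
(UPGMA) agglomeration, which yields an ultrametric dendrogram that can be
cut into cohorts or exported as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .pls import NIPALSPLS


@dataclass
class Dendrogram:
    """Merge list in scipy linkage form plus the leaf labels."""

    linkage: np.ndarray  # (n-1) x 4: node_a, node_b, height, size
    labels: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if (np.diff(heights) < -1e-9 * max(1.0, heights.max(initial=0.0))).any():
            raise ValueError("merge heights must be non-decreasing (not ultrametric)")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def bull_scores(
    model: NIPALSPLS,
    table: pd.DataFrame,
    x_columns: list[str],
    n_scores: int = 3,
) -> pd.DataFrame:
    """Per-bull mean score vector (t1..t_{n_scores})."""
    if model.W_star_.shape[1] < n_scores:
        raise ValueError(f"model has fewer than {n_scores} components")
    T = model.transform(table[x_columns].to_numpy(float))[:, :n_scores]
    df = pd.DataFrame(T, columns=[f"t{i+1}" for i in range(n_scores)])
    df["bull_id"] = table["bull_id"].to_numpy()
    return df.groupby("bull_id", sort=True).mean()


def upgma(distance_matrix: np.ndarray, labels: list[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a full distance matrix.

    The matrix must be symmetric with a zero diagonal and non-negative
    entries. Ties between equally close pairs are resolved by the backend
    deterministically (same input, same tree).
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("diagonal must be zero")
    n = D.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return Dendrogram(linkage=Z, labels=list(labels))


def cut_tree(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cut below the k-1 highest merges; groups numbered by size (desc).

    Returns a Series mapping leaf label -> group number (1 = largest).
    """
    n = dendrogram.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range 1..{n}")
    raw = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    # order by size descending, tie-break by first appearance
    order = sorted(sizes.index, key=lambda c: (-sizes[c], list(raw).index(c)))
    remap = {c: i + 1 for i, c in enumerate(order)}
    return pd.Series([remap[c] for c in raw], index=dendrogram.labels, name="group")


def cophenetic_matrix(dendrogram: Dendrogram) -> np.ndarray:
    """Full cophenetic distance matrix (merge height joining each pair)."""
    return squareform(hierarchy.cophenet(dendrogram.linkage))


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick export with ultrametric branch lengths.

    Each node sits at half its merge height, so two leaves merged at
    height h read "(A:h/2,B:h/2);".
    """
    Z = dendrogram.linkage
    n = dendrogram.n_leaves
    if n == 1:
        return f"{dendrogram.labels[0]}:0;"

    def height(node: int) -> float:
        return 0.0 if node < n else Z[node - n, 2] / 2.0

    def render(node: int) -> str:
        if node < n:
            return dendrogram.labels[node]
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = height(node)
        return (
            f"({render(a)}:{h - height(a):.10g},"
            f"{render(b)}:{h - height(b):.10g})"
        )

    return render(2 * n - 2) + ";"
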