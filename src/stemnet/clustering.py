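"""Country-level usage-profile hierarchical clustering.

Each country with at least ``min_publications`` studies gets a usage
profile: how many of its studies used each cell line.  Profile similarity
is Spearman rank correlation (counts carry rank structure; absolute volumes
differ by orders of magnitude between countries), turned into the distance
d = 1 - rho in [0, 2], and the profiles are agglomerated by average linkage
(UPGMA).  Merges at equal distance are resolved lexicographically by
country code so the dendrogram is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "ClusteringConfig",
    "Dendrogram",
    "country_usage_matrix",
    "spearman_distance_matrix",
    "average_linkage_tree",
]


@dataclass(frozen=True)
class ClusteringConfig:
    """Inclusion threshold and profile scale.

    ``min_publications`` drops small national corpora (spurious rank
    correlations); ``frequencies`` rescales each row to shares of the
    country's studies instead of raw counts (rank-invariant within a row,
    so the Spearman distances are unchanged; offered for inspection).
    """

    min_publications: int = 30
    frequencies: bool = False

    def validate(self) -> None:
        if self.min_publications < 1:
            raise ValueError("min_publications must be >= 1")


def country_usage_matrix(
    table: pd.DataFrame, config: ClusteringConfig | None = None
) -> pd.DataFrame:
    """Countries × lines matrix of per-country usage counts.

    Rows: countries with at least ``min_publications`` distinct studies.
    Columns: every line used by at least one retained country.  Entry =
    number of that country's studies using that line.
    """
    config = config or ClusteringConfig()
    config.validate()
    pubs = table.groupby("country")["study_id"].nunique()
    keep = pubs[pubs >= config.min_publications].index
    if len(keep) == 0:
        raise ValueError(
            f"no country reaches {config.min_publications} publications"
        )
    sub = table[table["country"].isin(keep)]
    mat = pd.crosstab(sub["country"], sub["line_id"])
    mat = mat.loc[sorted(keep), mat.columns[mat.sum(axis=0) > 0]]
    if config.frequencies:
        mat = mat.div(pubs[mat.index], axis=0)
    return mat


def spearman_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Spearman correlation between rows (mid-rank ties).

    Raises if any row is constant — its ranks have zero variance and the
    correlation is undefined; the error names the offending country.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to compute distances")
    values = matrix.to_numpy(dtype=float)
    for name, row in zip(matrix.index, values):
        if np.allclose(row, row[0]):
            raise ValueError(f"constant usage profile for {name!r}: "
                             "Spearman correlation undefined")
    rho, _ = spearmanr(values, axis=1)
    if len(matrix) == 2:  # spearmanr returns a scalar for a single pair
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


@dataclass
class Dendrogram:
    """Average-linkage merge history.

    ``merges`` is a list of (left, right, height, size) where left/right
    are sorted tuples of leaf labels and height is the average pairwise
    distance between the merged clusters.  Heights are non-decreasing
    (UPGMA on a metric-like matrix).
    """

    labels: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float, int]]

    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def to_newick(self) -> str:
        """Ultrametric Newick string; leaf depth = half the root height."""
        height_of: dict[tuple[str, ...], float] = {(l,): 0.0 for l in self.labels}
        text: dict[tuple[str, ...], str] = {(l,): l for l in self.labels}
        for left, right, h, _size in self.merges:
            node = tuple(sorted(left + right))
            bl_l = h / 2.0 - height_of[left] / 2.0
            bl_r = h / 2.0 - height_of[right] / 2.0
            text[node] = f"({text[left]}:{bl_l:.6g},{text[right]}:{bl_r:.6g})"
            height_of[node] = h
        root = tuple(sorted(self.labels))
        return text[root] + ";"

    def to_linkage(self) -> np.ndarray:
        """SciPy-style (n-1, 4) linkage matrix for plotting interop."""
        index = {(l,): i for i, l in enumerate(self.labels)}
        n = len(self.labels)
        out = np.zeros((len(self.merges), 4))
        for i, (left, right, h, size) in enumerate(self.merges):
            node = tuple(sorted(left + right))
            a, b = index[left], index[right]
            out[i] = [min(a, b), max(a, b), h, size]
            index[node] = n + i
        return out


def average_linkage_tree(distances: pd.DataFrame) -> Dendrogram:
    """UPGMA agglomeration of a symmetric distance matrix.

    At each step the pair of clusters at minimal average distance is
    merged; the distance from the merged cluster to any other is the
    size-weighted mean of the parts' distances.  Ties on distance are
    broken by the lexicographically smallest pair of cluster labels.
    """
    labels = [str(l) for l in distances.index]
    if list(distances.index) != list(distances.columns):
        raise ValueError("distance matrix must have matching index and columns")
    d = distances.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    clusters: dict[tuple[str, ...], int] = {(l,): 1 for l in labels}
    dist: dict[frozenset, float] = {}
    keys = list(clusters)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            dist[frozenset((keys[i], keys[j]))] = float(d[i, j])

    merges = []
    while len(clusters) > 1:
        best = None
        for pair, dd in dist.items():
            a, b = sorted(pair)
            cand = (dd, a, b)
            if best is None or cand < best:
                best = cand
        h, a, b = best
        na, nb = clusters.pop(a), clusters.pop(b)
        node = tuple(sorted(a + b))
        for other in list(clusters):
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((node, other))] = (na * da + nb * db) / (na + nb)
        dist.pop(frozenset((a, b)))
        clusters[node] = na + nb
        merges.append((a, b, h, na + nb))
    return Dendrogram(labels=labels, merges=merges)
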