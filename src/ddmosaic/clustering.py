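"""Multi-tissue MAF similarity: sqrt transform, Euclidean distances, UPGMA.

The clustering follows the transform used for the published heatmap
dendrogram: MAF fractions are square-root transformed (variance-stabilising
for binomial proportions), pairwise Euclidean distances are taken on the
transformed values, and samples are merged agglomeratively.  Average linkage
(UPGMA) is the default — the published analysis names the distance but not
the linkage, and UPGMA is the common default for such dendrograms — and the
resulting ultrametric tree is exportable as Newick.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _sch
from scipy.spatial.distance import pdist, squareform

from .errors import ClusteringError, ParameterError

__all__ = [
    "MAFMatrix",
    "Dendrogram",
    "build_maf_matrix",
    "sqrt_euclidean_distances",
    "hierarchical_cluster",
    "dendrogram_to_newick",
]

NA_POLICIES = ("drop_sample", "drop_feature", "pairwise")


@dataclass(frozen=True)
class MAFMatrix:
    """Rows = individual+tissue samples, columns = assays/variants."""

    values: pd.DataFrame
    na_policy: str
    missing_cells: tuple = ()  # (row, column) pairs dropped or left missing


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree in scipy linkage form plus leaf labels."""

    linkage: np.ndarray  # scipy (n-1, 4) linkage matrix
    labels: tuple

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def build_maf_matrix(samples, na_policy: str = "drop_feature") -> MAFMatrix:
    """Assemble a row-per-sample MAF matrix from tidy sample results.

    ``samples`` is a tidy table (DataFrame or list of mappings) with columns
    ``row_id``, ``feature``, ``value`` — ``value`` a MAF fraction or missing.
    A single-feature layout (one MAF per sample) and a multi-assay layout are
    both supported.  Missing cells are handled per ``na_policy``:
    ``drop_sample`` removes rows with any missing value, ``drop_feature``
    removes columns with any missing value (the conservative default),
    ``pairwise`` leaves them in place for pairwise-complete distances.
    """
    if na_policy not in NA_POLICIES:
        raise ParameterError(f"na_policy must be one of {NA_POLICIES}, got {na_policy!r}")
    df = pd.DataFrame(samples)
    required = {"row_id", "feature", "value"}
    if not required.issubset(df.columns):
        raise ParameterError(f"samples must have columns {sorted(required)}")
    if len(df) < 2:
        raise ClusteringError("need at least 2 samples to build a matrix")
    wide = df.pivot_table(index="row_id", columns="feature", values="value",
                          aggfunc="first", dropna=False)
    vals = wide.to_numpy(dtype=float)
    bad = (vals < -1e-12) | (vals > 1 + 1e-12)
    if np.any(bad & np.isfinite(vals)):
        raise ParameterError("MAF values must be fractions in [0, 1]")
    missing = [
        (str(r), str(c))
        for r, c in zip(*np.where(~np.isfinite(vals)))
        for r, c in [(wide.index[r], wide.columns[c])]
    ]
    if na_policy == "drop_sample":
        wide = wide.dropna(axis=0, how="any")
    elif na_policy == "drop_feature":
        wide = wide.dropna(axis=1, how="any")
    if wide.shape[0] < 2 or wide.shape[1] < 1:
        raise ClusteringError(
            f"fewer than 2 complete rows remain after na_policy={na_policy!r}"
        )
    return MAFMatrix(values=wide, na_policy=na_policy, missing_cells=tuple(missing))


def sqrt_euclidean_distances(matrix: MAFMatrix) -> pd.DataFrame:
    """Euclidean distances between rows of the sqrt-transformed matrix.

    d(i,j) = sqrt( sum_f (sqrt(m_if) - sqrt(m_jf))^2 ); the sqrt is applied
    to fractions in [0, 1].  Requires a complete matrix unless the matrix was
    built with the ``pairwise`` policy, in which case distances are computed
    over pairwise-complete features.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if np.any(vals[np.isfinite(vals)] < 0):
        raise ParameterError("negative MAF values are not allowed")
    if not np.all(np.isfinite(vals)):
        if matrix.na_policy != "pairwise":
            raise ParameterError("matrix still contains missing values; apply an na_policy first")
        root = np.sqrt(vals)
        n = root.shape[0]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                shared = np.isfinite(root[i]) & np.isfinite(root[j])
                if not shared.any():
                    raise ClusteringError(
                        f"rows {matrix.values.index[i]!r} and {matrix.values.index[j]!r} share no features"
                    )
                d[i, j] = d[j, i] = float(np.sqrt(((root[i, shared] - root[j, shared]) ** 2).sum()))
    else:
        d = squareform(pdist(np.sqrt(vals), metric="euclidean"))
    idx = matrix.values.index
    return pd.DataFrame(d, index=idx, columns=idx)


def hierarchical_cluster(d: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a precomputed distance matrix.

    Rows are ordered lexicographically by label before merging, so equal
    merge distances break ties toward the lexicographically smallest leaf.
    """
    if linkage not in ("average", "complete", "single"):
        raise ParameterError(f"linkage must be average/complete/single, got {linkage!r}")
    if not isinstance(d, pd.DataFrame):
        d = pd.DataFrame(np.asarray(d, dtype=float))
    arr = d.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] < 2:
        raise ParameterError("distance matrix must be square with >= 2 rows")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ParameterError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
        raise ParameterError("distance matrix must have a zero diagonal")
    order = np.argsort(d.index.astype(str))
    labels = tuple(str(x) for x in d.index[order])
    arr = arr[np.ix_(order, order)]
    Z = _sch.linkage(squareform(arr, checks=False), method=linkage)
    return Dendrogram(linkage=Z, labels=labels)


def cut_clusters(t: Dendrogram, n_clusters: int) -> dict:
    """Flat cluster membership {label: cluster_id} at a given cluster count."""
    flat = _sch.fcluster(t.linkage, t=n_clusters, criterion="maxclust")
    return {lab: int(c) for lab, c in zip(t.labels, flat)}


def _quote(label: str) -> str:
    safe = label.replace(" ", "_")
    if any(ch in safe for ch in "():;,'[]"):
        return "'" + safe.replace("'", "''") + "'"
    return safe


def dendrogram_to_newick(t: Dendrogram) -> str:
    """Serialise a dendrogram as a Newick string with branch lengths.

    Node depth is half the merge height, so under average linkage the tree
    is ultrametric: two leaves merged at height h sit at depth h/2 each.
    """
    n = len(t.labels)
    if n < 2:
        raise ParameterError("a dendrogram needs at least 2 leaves")
    heights = {i: 0.0 for i in range(n)}

    def node_str(idx: int) -> str:
        if idx < n:
            return _quote(t.labels[idx])
        a, b, h, _ = t.linkage[idx - n]
        a, b = int(a), int(b)
        parts = []
        for child in (a, b):
            bl = h / 2.0 - heights[child] / 2.0
            parts.append(f"{node_str(child)}:{bl:.10g}")
        heights[idx] = h
        return "(" + ",".join(parts) + ")"

    # record heights bottom-up before rendering the root
    for m, (a, b, h, _) in enumerate(t.linkage):
        heights[n + m] = float(h)
    return node_str(n + len(t.linkage) - 1) + ";"
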