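"""Expression normalisation, selection and temporal clustering.

Counts are normalised per library to reads-per-ten-million (RPTM;
``count / total_clean_reads * scale_factor``, scale configurable), miRNAs
with a maximum above the selection threshold in at least one library are
kept, profiles are transformed to log2 fold change versus the four-library
row mean (with a pseudocount), clustered with complete linkage on Euclidean
distance, and each cluster is labelled with a temporal archetype:

* A — monotone decreasing,
* B — peak in library 2,
* C — peak in library 2 or 3 (the non-B peaked cluster),
* D — monotone increasing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

from .errors import ClusteringError, NormalizationError

DEFAULT_SCALE = 1e7  # reads per ten million


def normalize_rptm(
    counts: pd.DataFrame,
    library_totals: dict[str, int] | pd.Series,
    scale_factor: float = DEFAULT_SCALE,
) -> pd.DataFrame:
    """Elementwise count / library_total * scale_factor.

    ``counts`` is miRNA x library; column order is preserved.
    """
    totals = pd.Series(library_totals).reindex(counts.columns)
    if totals.isna().any():
        missing = list(totals.index[totals.isna()])
        raise NormalizationError(f"missing library totals for {missing}")
    if (totals <= 0).any():
        raise NormalizationError("library totals must be positive")
    return counts.div(totals, axis=1) * scale_factor


def select_expressed(matrix: pd.DataFrame, min_rptm: float = 100.0) -> pd.DataFrame:
    """Keep rows whose maximum across libraries exceeds ``min_rptm`` (strict >)."""
    kept = matrix[matrix.max(axis=1) > min_rptm]
    kept.attrs["n_kept"] = len(kept)
    kept.attrs["n_dropped"] = len(matrix) - len(kept)
    return kept


def logfc_vs_mean(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2((x + p) / (row mean + p)) — fold change versus the library average."""
    mean = matrix.mean(axis=1)
    return np.log2(matrix.add(pseudocount).div(mean + pseudocount, axis=0))


def _label_centroid(centroid: np.ndarray) -> str:
    d = np.diff(centroid)
    if np.all(d < 0):
        return "A"
    if np.all(d > 0):
        return "D"
    am = int(np.argmax(centroid))
    if am == 1:
        return "B"
    if am == 2:
        return "C"
    return "unclassified"


def cluster_profiles(
    matrix: pd.DataFrame,
    k: int = 4,
    pseudocount: float = 1.0,
    metric: str = "euclidean",
):
    """Complete-linkage clustering of logfc profiles, cut into k clusters.

    Returns ``(labels, assignments, Z, lfc)`` where ``labels`` maps miRNA id
    to class A/B/C/D/unclassified, ``assignments`` maps id to cluster number,
    ``Z`` is the scipy linkage matrix and ``lfc`` the transformed profiles.
    Cluster labelling is by centroid shape; when two clusters both peak in
    library 2, the first (by smallest row index) is B and the other C.
    """
    if len(matrix) < k:
        raise ClusteringError(f"{len(matrix)} rows < k={k}")
    lfc = logfc_vs_mean(matrix, pseudocount)
    if metric == "pearson":
        dist = pdist(lfc.values, metric="correlation")
    else:
        dist = pdist(lfc.values, metric="euclidean")
    Z = linkage(dist, method="complete")
    flat = fcluster(Z, t=k, criterion="maxclust")

    labels: dict[str, str] = {}
    # clusters in deterministic order: by first member's row position
    order = sorted(set(flat), key=lambda c: int(np.argmax(flat == c)))
    b_used = False
    for c in order:
        members = lfc.index[flat == c]
        centroid = lfc.loc[members].mean(axis=0).values
        lab = _label_centroid(centroid)
        if lab == "B":
            if b_used:
                lab = "C"
            b_used = True
        for m in members:
            labels[m] = lab
    assignments = {rid: int(c) for rid, c in zip(matrix.index, flat)}
    return labels, assignments, Z, lfc


def dendrogram_newick(Z: np.ndarray, ids: list[str]) -> str:
    """Newick text for the scipy linkage tree (branch lengths = merge heights)."""
    root = to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(root, root.dist) + ";"
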