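"""Shared hierarchical-clustering core: Ward + silhouette-selected k.

Used for both regulator clustering (precomputed Jaccard distances) and
sample clustering (Pearson distances).  Ward's minimum-variance update is
applied to the supplied distance matrix via scipy's linkage; the number of
clusters is the one maximizing the average silhouette width computed from
the same distance matrix (ties resolved toward the smallest k).
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score


def validate_distance_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have zero diagonal")
    if (d < 0).any():
        raise ValueError("distance matrix must be non-negative")
    return (d + d.T) / 2.0


def ward_silhouette(
    distance: np.ndarray,
    k_min: int = 2,
    k_max: int | None = None,
    method: str = "ward",
    k: int | None = None,
) -> tuple[np.ndarray, int, dict[int, float], np.ndarray]:
    """Cut a Ward tree at the silhouette-optimal number of clusters.

    Parameters
    ----------
    distance
        Square symmetric distance matrix.
    k_min, k_max
        Candidate range for the number of clusters; ``k_max`` defaults to
        ``min(30, n - 1)``.  Silhouette is computed from the same matrix;
        the smallest k attaining the maximum average silhouette wins.
    k
        Fix the number of clusters instead of searching (silhouette is
        still reported for that single k).

    Returns
    -------
    (labels, k, silhouette_by_k, linkage_matrix)
        ``labels`` are 1-based cluster indices.
    """
    d = validate_distance_matrix(distance)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 items to cluster (silhouette undefined)")
    z = linkage(squareform(d, checks=False), method=method)
    if k is not None:
        if not (2 <= k <= n - 1):
            raise ValueError(f"k must be in [2, {n - 1}], got {k}")
        candidates = [k]
    else:
        if k_min < 2:
            raise ValueError("k_min must be >= 2")
        if k_max is None:
            k_max = min(30, n - 1)
        if k_max >= n:
            raise ValueError("k_max must be < number of items")
        if k_max < k_min:
            raise ValueError("k_max must be >= k_min")
        candidates = list(range(k_min, k_max + 1))
    sil: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for kk in candidates:
        lab = fcluster(z, t=kk, criterion="maxclust")
        labelings[kk] = lab
        if len(np.unique(lab)) < 2:
            sil[kk] = float("-inf")  # degenerate cut, never selected
            continue
        sil[kk] = float(silhouette_score(d, lab, metric="precomputed"))
    best_k = candidates[0]
    for kk in candidates[1:]:
        if sil[kk] > sil[best_k] + 1e-12:
            best_k = kk
    labels = labelings[best_k]
    # renumber to 1..k in order of first appearance for determinism
    remap: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[i] = remap[lab]
    sil_clean = {kk: (v if np.isfinite(v) else float("nan")) for kk, v in sil.items()}
    return out, best_k, sil_clean, z


def linkage_to_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = to_tree(z)

    def rec(node, parent_dist: float) -> str:
        blen = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{blen:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{blen:.6g}"

    return f"{rec(tree, tree.dist)};"
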