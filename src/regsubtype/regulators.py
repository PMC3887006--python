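"""Clustering regulators by overlap of their downstream target sets.

Regulators identified across all samples are pooled and clustered with
Ward's method on pairwise Jaccard distances between their measured
downstream target sets, so that redundant family members acting on one
transcriptional program (e.g. paralogous transcription factors) fall into
one cluster.  The number of clusters maximizes the average silhouette.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cluster import linkage_to_newick, ward_silhouette
from .network import RegulatoryNetwork

logger = logging.getLogger(__name__)


def jaccard_distance(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """1 − |A∩B| / |A∪B| for two non-empty gene sets."""
    a, b = frozenset(set_a), frozenset(set_b)
    if not a or not b:
        raise ValueError("jaccard_distance requires non-empty sets")
    return 1.0 - len(a & b) / len(a | b)


def regulator_distance_matrix(
    regulators: Sequence[str],
    network: RegulatoryNetwork,
    measured_genes: Iterable[str],
) -> pd.DataFrame:
    """Pairwise Jaccard distances between measured downstream sets.

    Regulators whose measured target set is empty are excluded with a
    warning; the returned matrix is indexed by the retained regulators in
    the given order.
    """
    measured = frozenset(measured_genes)
    sets: dict[str, frozenset[str]] = {}
    excluded: list[str] = []
    for r in regulators:
        t = network.downstream_targets(r, measured)
        if t:
            sets[r] = t
        else:
            excluded.append(r)
    if excluded:
        logger.warning(
            "excluding %d regulators with no measured targets: %s",
            len(excluded), excluded,
        )
    kept = [r for r in regulators if r in sets]
    if not kept:
        raise ValueError("no regulator has a measured downstream target")
    genes = sorted(set().union(*sets.values()))
    gpos = {g: i for i, g in enumerate(genes)}
    m = np.zeros((len(kept), len(genes)), dtype=bool)
    for i, r in enumerate(kept):
        for g in sets[r]:
            m[i, gpos[g]] = True
    sizes = m.sum(axis=1).astype(float)
    inter = (m.astype(np.int64) @ m.T.astype(np.int64)).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=kept, columns=kept)


@dataclass
class RegulatorClustering:
    """Jaccard-distance Ward clustering of the regulator union."""

    regulator_ids: list[str]
    distance: pd.DataFrame
    labels: dict[str, int]
    k: int
    silhouette_by_k: dict[int, float]
    linkage_matrix: np.ndarray

    @property
    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for lab in self.labels.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def members(self, cluster: int) -> list[str]:
        return [r for r in self.regulator_ids if self.labels[r] == cluster]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "regulator": self.regulator_ids,
                "cluster": [self.labels[r] for r in self.regulator_ids],
            }
        )

    def silhouette_frame(self) -> pd.DataFrame:
        ks = sorted(self.silhouette_by_k)
        return pd.DataFrame(
            {"k": ks, "avg_silhouette": [self.silhouette_by_k[k] for k in ks]}
        )

    def to_newick(self) -> str:
        return linkage_to_newick(self.linkage_matrix, self.regulator_ids)


def cluster_with_optimal_k(
    distance: pd.DataFrame | np.ndarray,
    k_min: int = 2,
    k_max: int | None = None,
    linkage: str = "ward",
    k: int | None = None,
) -> RegulatorClustering:
    """Ward-cluster a regulator distance matrix at the silhouette-best k.

    ``k_max`` defaults to ``min(30, n_regulators − 1)``; ties in average
    silhouette resolve to the smallest k.  ``linkage="average"`` is the
    fallback for callers preferring a linkage defined for arbitrary
    dissimilarities.
    """
    if isinstance(distance, pd.DataFrame):
        ids = [str(c) for c in distance.columns]
        d = distance.to_numpy(dtype=float)
    else:
        d = np.asarray(distance, dtype=float)
        ids = [f"item{i}" for i in range(d.shape[0])]
    labels, best_k, sil, z = ward_silhouette(
        d, k_min=k_min, k_max=k_max, method=linkage, k=k
    )
    return RegulatorClustering(
        regulator_ids=ids,
        distance=pd.DataFrame(d, index=ids, columns=ids),
        labels={r: int(l) for r, l in zip(ids, labels)},
        k=int(best_k),
        silhouette_by_k=sil,
        linkage_matrix=z,
    )
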