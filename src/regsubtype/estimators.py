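"""scikit-learn style estimators wrapping the pipeline stages.

`RegulatorActivityTransformer` turns a samples × genes log-ratio matrix
into a samples × regulator-cluster activity matrix (fit = per-sample
enrichment + regulator clustering on the training samples; transform =
activity scoring of any samples over the learned clusters), and
`WardSilhouetteClustering` is the Ward + silhouette-selected-k clusterer
used both for regulators (precomputed distances) and samples (Pearson
distance on feature rows).  Both follow the sklearn estimator contract
(get_params/set_params, fitted attributes with trailing underscores) and
compose with sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin

from .activity import cluster_activity_matrix
from .cluster import ward_silhouette
from .expression import LogRatioMatrix
from .network import RegulatoryNetwork
from .regulators import cluster_with_optimal_k, regulator_distance_matrix
from .snea import SneaConfig, snea_all_samples


def _as_frame(X, feature_names=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (samples × features)")
    if feature_names is None:
        raise ValueError(
            "array input needs feature (gene) names; pass a DataFrame or "
            "set feature_names"
        )
    return pd.DataFrame(X, columns=list(feature_names))


class RegulatorActivityTransformer(TransformerMixin, BaseEstimator):
    """Samples × genes log-ratios → samples × regulator-cluster activities.

    Parameters
    ----------
    network : RegulatoryNetwork
        Regulator→target network providing downstream sets and
        connectivity weights.
    top_n, p_threshold, min_targets, weighting, alternative,
    exclude_targets_from_background
        Enrichment-test settings (see :class:`~regsubtype.snea.SneaConfig`).
    k_min, k_max, linkage
        Regulator-clustering settings; the number of clusters maximizes
        the average silhouette of the Jaccard-distance matrix.
    feature_names : sequence of str, optional
        Gene ids for plain-array input (unused for DataFrame input).

    Attributes
    ----------
    regulators_ : list of str
        Union of significant regulators over the training samples.
    clustering_ : RegulatorClustering
        Jaccard/Ward clustering of ``regulators_``.
    n_clusters_ : int
    records_ : SneaResult
        Per-sample enrichment records from fit.
    """

    def __init__(
        self,
        network: RegulatoryNetwork | None = None,
        top_n: int = 100,
        p_threshold: float = 0.05,
        min_targets: int = 3,
        weighting: str = "connectivity",
        alternative: str = "two_sided",
        exclude_targets_from_background: bool = False,
        k_min: int = 2,
        k_max: int | None = None,
        linkage: str = "ward",
        feature_names=None,
    ):
        self.network = network
        self.top_n = top_n
        self.p_threshold = p_threshold
        self.min_targets = min_targets
        self.weighting = weighting
        self.alternative = alternative
        self.exclude_targets_from_background = exclude_targets_from_background
        self.k_min = k_min
        self.k_max = k_max
        self.linkage = linkage
        self.feature_names = feature_names

    def _snea_config(self) -> SneaConfig:
        return SneaConfig(
            top_n=self.top_n,
            p_threshold=self.p_threshold,
            min_targets=self.min_targets,
            weighting=self.weighting,
            alternative=self.alternative,
            exclude_targets_from_background=self.exclude_targets_from_background,
        )

    def fit(self, X, y=None):
        if self.network is None:
            raise ValueError("network must be provided")
        frame = _as_frame(X, self.feature_names)
        lrm = LogRatioMatrix(
            values=frame.T,
            control_profile=pd.Series(0.0, index=frame.columns),
        )
        self.records_ = snea_all_samples(lrm, self.network, self._snea_config())
        regulators = self.records_.regulators
        if len(regulators) < 3:
            raise ValueError(
                f"only {len(regulators)} significant regulators found; "
                "cannot cluster"
            )
        dist = regulator_distance_matrix(
            regulators, self.network, frame.columns
        )
        self.clustering_ = cluster_with_optimal_k(
            dist, k_min=self.k_min, k_max=self.k_max, linkage=self.linkage
        )
        self.regulators_ = list(self.clustering_.regulator_ids)
        self.n_clusters_ = self.clustering_.k
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "clustering_"):
            raise ValueError("transformer is not fitted")
        frame = _as_frame(X, self.feature_names)
        lrm = LogRatioMatrix(
            values=frame.T,
            control_profile=pd.Series(0.0, index=frame.columns),
        )
        am = cluster_activity_matrix(self.clustering_, lrm, self.network)
        return am.c_values.T  # samples × clusters

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "clustering_"):
            raise ValueError("transformer is not fitted")
        return np.array(
            [f"cluster{j}" for j in sorted(set(self.clustering_.labels.values()))]
        )


class WardSilhouetteClustering(ClusterMixin, BaseEstimator):
    """Ward clustering with silhouette-selected number of clusters.

    ``metric="pearson"`` treats rows of X as sample profiles and clusters
    them on 1 − correlation distance; ``metric="precomputed"`` expects a
    square distance matrix.  ``n_clusters=None`` searches ``k_min..k_max``
    for the maximum average silhouette (ties → smallest k).

    Attributes
    ----------
    labels_ : ndarray of 1-based cluster indices
    k_ : chosen number of clusters
    silhouette_by_k_ : dict k → average silhouette width
    """

    def __init__(
        self,
        n_clusters: int | None = None,
        metric: str = "pearson",
        k_min: int = 2,
        k_max: int | None = None,
        linkage: str = "ward",
    ):
        self.n_clusters = n_clusters
        self.metric = metric
        self.k_min = k_min
        self.k_max = k_max
        self.linkage = linkage

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(dtype=float)
        if self.metric == "precomputed":
            d = X
        elif self.metric == "pearson":
            if X.shape[0] < 3:
                raise ValueError("need at least 3 samples")
            sd = X.std(axis=1)
            if (sd == 0).any():
                raise ValueError(
                    f"constant sample profile at rows {list(np.flatnonzero(sd == 0))}"
                )
            d = 1.0 - np.corrcoef(X)
            np.fill_diagonal(d, 0.0)
            d = np.clip(d, 0.0, 2.0)
        else:
            raise ValueError("metric must be 'pearson' or 'precomputed'")
        labels, k, sil, z = ward_silhouette(
            d, k_min=self.k_min, k_max=self.k_max, method=self.linkage,
            k=self.n_clusters,
        )
        self.labels_ = labels
        self.k_ = int(k)
        self.silhouette_by_k_ = sil
        self.linkage_matrix_ = z
        self.n_features_in_ = X.shape[1]
        return self
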