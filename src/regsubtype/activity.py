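"""Activity scoring of regulators and regulator clusters.

Each regulator i contributes, per sample, K_i = median of its measured
downstream log-ratios × the number of those genes; the activity of a
cluster j of regulators is C_j = Σ K_i over its N_j members.  Evaluating K
for every regulator in every sample (not only where it was individually
significant) yields the dense clusters × samples activity matrix used for
patient clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .expression import LogRatioMatrix
from .network import RegulatoryNetwork
from .regulators import RegulatorClustering


def regulator_k_value(
    log_ratio_column: pd.Series, downstream_measured: Iterable[str]
) -> float:
    """median(downstream log-ratios) × number of downstream genes."""
    down = sorted(frozenset(downstream_measured))
    if not down:
        raise ValueError("downstream set is empty")
    missing = [g for g in down if g not in log_ratio_column.index]
    if missing:
        raise KeyError(f"downstream genes absent from column: {missing}")
    vals = log_ratio_column.loc[down].to_numpy(dtype=float)
    return float(np.median(vals) * len(down))


@dataclass
class ActivityMatrix:
    """Per-regulator K values and per-cluster C values, per sample."""

    k_values: pd.DataFrame  # regulators × samples
    c_values: pd.DataFrame  # clusters × samples
    cluster_sizes: dict[int, int]

    @property
    def n_clusters(self) -> int:
        return self.c_values.shape[0]

    @property
    def sample_ids(self) -> pd.Index:
        return self.c_values.columns


def cluster_activity_matrix(
    clustering: RegulatorClustering,
    log_ratios: LogRatioMatrix,
    network: RegulatoryNetwork,
    normalize_by_size: bool = False,
) -> ActivityMatrix:
    """Compute K for every (regulator, sample) and sum into cluster rows.

    The downstream set of a regulator is its measured targets under the
    network's active relation filter — the same set the enrichment test
    used.  ``normalize_by_size`` divides each C row by the cluster size
    N_j (off by default: cluster activity is the raw sum of K values).
    """
    genes = frozenset(log_ratios.gene_ids)
    samples = list(log_ratios.sample_ids)
    values = log_ratios.values
    k_rows = {}
    for reg in clustering.regulator_ids:
        if reg not in set(network.seeds):
            raise ValueError(f"clustered regulator {reg!r} missing from network")
        down = sorted(network.downstream_targets(reg, genes))
        if not down:
            raise ValueError(f"regulator {reg!r} has no measured downstream targets")
        sub = values.loc[down].to_numpy(dtype=float)
        k_rows[reg] = np.median(sub, axis=0) * len(down)
    k_values = pd.DataFrame.from_dict(k_rows, orient="index", columns=samples)
    k_values = k_values.loc[clustering.regulator_ids]

    cluster_ids = sorted(set(clustering.labels.values()))
    c_rows = {}
    sizes: dict[int, int] = {}
    for cj in cluster_ids:
        members = clustering.members(cj)
        sizes[cj] = len(members)
        row = k_values.loc[members].sum(axis=0)
        if normalize_by_size:
            row = row / len(members)
        c_rows[cj] = row
    c_values = pd.DataFrame.from_dict(c_rows, orient="index", columns=samples)
    c_values.index.name = "cluster"
    return ActivityMatrix(k_values=k_values, c_values=c_values, cluster_sizes=sizes)
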