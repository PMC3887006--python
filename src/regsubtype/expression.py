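"""Expression matrices, preprocessing and per-sample log-ratios.

The pipeline compares every disease sample against one averaged control
profile: intensities are log-transformed, each array (sample column) is
standardized to zero mean and unit variance, synonymous probesets are
collapsed to the probeset with maximum mean intensity, and per-gene
log-ratios are formed as the difference (in log space) between a disease
sample and the mean of the control columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_STATES = ("raw", "logged", "standardized")


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with group metadata.

    ``groups`` maps every sample to a group label; exactly one group label
    is the designated control.  ``state`` tracks preprocessing progress.
    """

    values: pd.DataFrame
    groups: pd.Series
    control_group: str
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown state: {self.state!r}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group annotation: {sorted(missing)}")
        self.groups = self.groups.loc[self.values.columns]
        if self.control_group not in set(self.groups):
            raise ValueError(
                f"control group {self.control_group!r} has no samples"
            )
        if self.state != "raw" and self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids after preprocessing")
        if self.state == "standardized":
            v = self.values.to_numpy()
            if not (
                np.allclose(v.mean(axis=0), 0.0, atol=1e-8)
                and np.allclose(v.var(axis=0), 1.0, atol=1e-8)
            ):
                raise ValueError("standardized state requires per-sample mean 0, variance 1")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> list[str]:
        if group not in set(self.groups):
            raise KeyError(f"unknown group: {group!r}")
        return [s for s in self.sample_ids if self.groups[s] == group]

    @property
    def control_samples(self) -> list[str]:
        return self.samples_in_group(self.control_group)

    @property
    def disease_samples(self) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] != self.control_group]


@dataclass
class LogRatioMatrix:
    """Genes × disease-samples log-ratios against the averaged control."""

    values: pd.DataFrame
    control_profile: pd.Series
    sample_groups: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def read_expression(
    path: str | Path, groups_path: str | Path, control_label: str
) -> ExpressionMatrix:
    """Read an expression TSV (first column ``gene``) and a groups TSV.

    The groups file has columns ``sample`` and ``group``; every sample
    column of the matrix must be annotated.  Duplicate gene rows are
    accepted at this stage (they are collapsed by :func:`preprocess`).
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    if not all(np.issubdtype(dt, np.number) for dt in values.dtypes):
        bad = [c for c, dt in values.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise ValueError(f"non-numeric expression columns: {bad}")
    gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
    required = {"sample", "group"}
    if not required.issubset(gdf.columns):
        raise ValueError(f"groups file must have columns {sorted(required)}")
    if gdf["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in groups file")
    groups = pd.Series(gdf["group"].values, index=gdf["sample"].values)
    return ExpressionMatrix(values=values, groups=groups, control_group=control_label)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a probe→gene TSV with columns ``probe`` and ``gene``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe", "gene"}.issubset(df.columns):
        raise ValueError("probe map must have columns ['probe', 'gene']")
    return dict(zip(df["probe"], df["gene"]))


def _collapse_probesets(
    values: pd.DataFrame, probe_to_gene: Mapping[str, str] | None
) -> pd.DataFrame:
    """Keep, per gene, the probeset with maximum mean intensity.

    The winner is decided on raw-scale mean intensity across all samples,
    before standardization; ties break lexicographically by probeset id,
    then by row position.  Probesets mapping to no gene are dropped with a
    warning.  With no explicit map, duplicated row ids are collapsed using
    the identity mapping.
    """
    if probe_to_gene is None:
        if not values.index.duplicated().any():
            return values
        probe_to_gene = {p: p for p in values.index}
    mapped = values.index.map(lambda p: probe_to_gene.get(p))
    n_unmapped = int(pd.isna(mapped).sum())
    if n_unmapped:
        logger.warning("dropping %d probesets mapping to no gene", n_unmapped)
    keep_rows: list[int] = []
    means = values.to_numpy().mean(axis=1)
    best: dict[str, tuple[float, str, int]] = {}
    for pos, (probe, gene) in enumerate(zip(values.index, mapped)):
        if gene is None or (isinstance(gene, float) and np.isnan(gene)):
            continue
        key = (-means[pos], str(probe), pos)
        if gene not in best or key < best[gene]:
            best[gene] = key
    order = sorted(best, key=lambda g: best[g][2])
    rows = [best[g][2] for g in order]
    out = values.iloc[rows].copy()
    out.index = pd.Index(order, name=values.index.name)
    return out


def standardize_columns(values: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each sample column to mean 0, variance 1 (ddof=0)."""
    v = values.to_numpy(dtype=float)
    mu = v.mean(axis=0)
    sd = v.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero variance column: {list(values.columns[zero])}"
        )
    return pd.DataFrame((v - mu) / sd, index=values.index, columns=values.columns)


def preprocess(
    matrix: ExpressionMatrix,
    log_base: float = 2.0,
    already_logged: bool = False,
    probe_to_gene: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Collapse probesets, log-transform and standardize per sample.

    Probeset collapse keeps the single probeset with maximum mean raw
    intensity per gene (computed before standardization).  Rows containing
    missing values are dropped with a logged count.  Output columns have
    mean 0 and variance 1 within 1e-8.
    """
    if matrix.state != "raw":
        raise ValueError(f"preprocess expects a raw-state matrix, got {matrix.state!r}")
    values = matrix.values
    n_na = int(values.isna().any(axis=1).sum())
    if n_na:
        logger.warning("dropping %d gene rows with missing values", n_na)
        values = values.dropna(axis=0)
    values = _collapse_probesets(values, probe_to_gene)
    if already_logged:
        logged = values.astype(float)
    else:
        if (values.to_numpy() <= 0).any():
            raise ValueError(
                "non-positive intensities cannot be log-transformed; "
                "pass already_logged=True for pre-logged data"
            )
        logged = pd.DataFrame(
            np.log(values.to_numpy(dtype=float)) / np.log(log_base),
            index=values.index,
            columns=values.columns,
        )
    std = standardize_columns(logged)
    return ExpressionMatrix(
        values=std,
        groups=matrix.groups,
        control_group=matrix.control_group,
        state="standardized",
    )


def group_average(matrix: ExpressionMatrix, group: str) -> pd.Series:
    """Per-gene mean profile over a group's samples (the "average patient")."""
    samples = matrix.samples_in_group(group)
    return matrix.values[samples].mean(axis=1)


def compute_log_ratios(matrix: ExpressionMatrix) -> LogRatioMatrix:
    """Log-ratios of every non-control sample against the averaged control.

    On standardized log-scale data the log-ratio is the difference between
    a sample's value and the mean of the control columns.
    """
    if matrix.state != "standardized":
        raise ValueError("compute_log_ratios expects a standardized matrix")
    control = matrix.control_samples
    if not control:
        raise ValueError("control group is empty")
    disease = matrix.disease_samples
    if not disease:
        raise ValueError("no samples outside the control group")
    profile = matrix.values[control].mean(axis=1)
    lr = matrix.values[disease].sub(profile, axis=0)
    return LogRatioMatrix(
        values=lr,
        control_profile=profile,
        sample_groups=matrix.groups.loc[disease],
    )


def variance_support_check(matrix: ExpressionMatrix) -> float:
    """Fraction of genes with lower variance in controls than in disease.

    A sanity check supporting the averaged-control construction: if
    controls are homogeneous relative to the pooled disease samples, the
    fraction is well above 0.5.
    """
    control = matrix.samples_in_group(matrix.control_group)
    disease = matrix.disease_samples
    if len(control) < 2 or len(disease) < 2:
        raise ValueError("need >=2 control and >=2 non-control samples")
    var_c = matrix.values[control].var(axis=1, ddof=1)
    var_d = matrix.values[disease].var(axis=1, ddof=1)
    return float((var_c < var_d).mean())
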