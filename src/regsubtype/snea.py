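"""Per-sample Sub-Network Enrichment Analysis (SNEA).

For each regulator (seed) and each disease sample, the distribution of
log-ratios of the seed's measured downstream targets is compared with the
background distribution of all measured genes' log-ratios in that sample
using a connectivity-weighted Mann–Whitney U test: every gene contributes
with multiplicity equal to its network connectivity, which damps the
influence of hub genes that appear downstream of many regulators.  Seeds
are ranked by ascending p-value and at most ``top_n`` records with
``p < p_threshold`` are retained per sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .expression import LogRatioMatrix
from .network import RegulatoryNetwork

logger = logging.getLogger(__name__)

_ALTERNATIVES = ("two_sided", "greater", "less")
_WEIGHTINGS = ("connectivity", "downstream", "none")


@dataclass(frozen=True)
class SneaConfig:
    """Parameters of the per-sample enrichment run.

    ``weighting="connectivity"`` replicates both the downstream and the
    background distribution by gene connectivity; ``"downstream"`` weights
    only the downstream set; ``"none"`` is the plain unweighted test.
    """

    top_n: int = 100
    p_threshold: float = 0.05
    min_targets: int = 3
    weighting: str = "connectivity"
    alternative: str = "two_sided"
    exclude_targets_from_background: bool = False
    exact_limit: int = 10_000

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.min_targets < 1:
            raise ValueError("min_targets must be >= 1")
        if self.weighting not in _WEIGHTINGS:
            raise ValueError(f"weighting must be one of {_WEIGHTINGS}")
        if self.alternative not in _ALTERNATIVES:
            raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One (sample, regulator) SNEA result."""

    sample_id: str
    regulator_id: str
    downstream_measured: frozenset[str]
    n_down: int
    u_statistic: float
    p_value: float
    rank: int


def _validate_weights(weights: np.ndarray, side: str) -> None:
    if weights.size == 0:
        raise ValueError(f"empty side: {side}")
    if not np.issubdtype(weights.dtype, np.integer):
        if not np.allclose(weights, np.round(weights)):
            raise ValueError(f"weights_{side} must be positive integers")
    if (weights <= 0).any():
        raise ValueError(f"weights_{side} must be positive")


def _exact_pvalues(ranks: np.ndarray, n_a: int) -> tuple[float, float]:
    """Exact conditional permutation tail probabilities of the rank sum.

    Returns ``(P(R_A <= r_obs), P(R_A >= r_obs))`` where the distribution
    of the rank sum of side A is taken over all equally likely subsets of
    size ``n_a`` of the pooled (midrank-tied) observations.  Computed by a
    knapsack-style dynamic program over doubled midranks on the smaller
    side; ties are handled exactly because midranks are shared.
    """
    n = ranks.size
    n_b = n - n_a
    # work on the smaller side; complement at the end
    if n_a <= n_b:
        m, flip = n_a, False
    else:
        m, flip = n_b, True
    r2 = np.round(2 * ranks).astype(np.int64)
    obs2 = int(np.round(2 * ranks[:n_a].sum()))
    if flip:
        obs2 = int(r2.sum()) - obs2  # rank sum of side B
    max2 = int(np.sort(r2)[-m:].sum())
    min2 = int(np.sort(r2)[:m].sum())
    dp = np.zeros((m + 1, max2 + 1))
    dp[0, 0] = 1.0
    for i, r in enumerate(r2):
        kmax = min(i + 1, m)
        for k in range(kmax, 0, -1):
            src = dp[k - 1, : max2 + 1 - r]
            if src.any():
                dp[k, r : r + src.size] += src
    dist = dp[m]
    total = dist.sum()
    sums = np.arange(max2 + 1)
    p_le = float(dist[sums <= obs2].sum() / total)
    p_ge = float(dist[sums >= obs2].sum() / total)
    if flip:
        # R_A = T - R_B, so tails swap
        p_le, p_ge = p_ge, p_le
    return p_le, p_ge


def weighted_mann_whitney(
    values_a: Sequence[float],
    weights_a: Sequence[int],
    values_b: Sequence[float],
    weights_b: Sequence[int],
    alternative: str = "two_sided",
    exact_limit: int = 10_000,
) -> tuple[float, float]:
    """Mann–Whitney U test with integer replication weights.

    The result is identical to the standard test applied to the value
    lists with every value explicitly replicated ``weight`` times.  The
    p-value is exact (full enumeration of the conditional permutation
    distribution, ties included) whenever the replicated group-size
    product ``n_a * n_b`` is at most ``exact_limit``; otherwise a normal
    approximation with tie and continuity correction is used.

    Returns
    -------
    (u_statistic, p_value)
        ``u_statistic`` is the U of side A (number of (a, b) pairs with
        ``a > b``, ties counting one half).
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    wa = np.asarray(weights_a)
    wb = np.asarray(weights_b)
    if va.shape != wa.shape or vb.shape != wb.shape:
        raise ValueError("values and weights must have equal lengths")
    _validate_weights(wa, "a")
    _validate_weights(wb, "b")
    a = np.repeat(va, wa.astype(int))
    b = np.repeat(vb, wb.astype(int))
    n_a, n_b = a.size, b.size
    ranks = rankdata(np.concatenate([a, b]))
    u = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)

    if n_a * n_b <= exact_limit:
        p_le, p_ge = _exact_pvalues(ranks, n_a)
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return u, p

    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    s2 = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if s2 <= 0:
        return u, 1.0  # all observations tied
    sd = math.sqrt(s2)
    if alternative == "greater":
        z = (u - mu - 0.5) / sd
        p = float(norm.sf(z))
    elif alternative == "less":
        z = (u - mu + 0.5) / sd
        p = float(norm.cdf(z))
    else:
        z = (abs(u - mu) - 0.5) / sd
        p = float(min(1.0, 2.0 * norm.sf(z)))
    return u, p


def snea_one_sample(
    log_ratios: pd.Series,
    network: RegulatoryNetwork,
    config: SneaConfig | None = None,
    sample_id: str | None = None,
) -> list[EnrichmentRecord]:
    """Run SNEA on one sample's log-ratio column.

    Every seed with at least ``min_targets`` measured downstream targets
    is tested against the background of all measured genes (the seed's
    own targets included unless ``exclude_targets_from_background``).
    Records are ranked by ascending p-value (ties by regulator id) and
    truncated to ``top_n`` with ``p < p_threshold``.
    """
    config = config or SneaConfig()
    sid = sample_id if sample_id is not None else str(log_ratios.name)
    genes = log_ratios.index
    if genes.duplicated().any():
        raise ValueError("duplicate gene ids in log-ratio column")
    values = log_ratios.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(genes)}
    conn = network.connectivity_map()
    weights = np.fromiter((conn.get(g, 1) for g in genes), dtype=np.int64, count=len(genes))
    ones = np.ones(len(genes), dtype=np.int64)
    bg_weights = weights if config.weighting == "connectivity" else ones
    down_weighted = config.weighting in ("connectivity", "downstream")

    tested: list[tuple[float, str, float, frozenset[str]]] = []
    for seed in network.seeds:
        down = network.downstream_targets(seed, pos)
        if len(down) < config.min_targets:
            continue
        idx = np.fromiter((pos[g] for g in sorted(down)), dtype=np.int64, count=len(down))
        a_vals = values[idx]
        a_w = weights[idx] if down_weighted else ones[idx]
        if config.exclude_targets_from_background:
            mask = np.ones(len(genes), dtype=bool)
            mask[idx] = False
            b_vals, b_w = values[mask], bg_weights[mask]
        else:
            b_vals, b_w = values, bg_weights
        u, p = weighted_mann_whitney(
            a_vals, a_w, b_vals, b_w,
            alternative=config.alternative,
            exact_limit=config.exact_limit,
        )
        tested.append((p, seed, u, frozenset(down)))
    if not tested:
        logger.info("sample %s: no seed with >= %d measured targets", sid, config.min_targets)
        return []
    tested.sort(key=lambda t: (t[0], t[1]))
    records = []
    for rank, (p, seed, u, down) in enumerate(tested, start=1):
        if p >= config.p_threshold or rank > config.top_n:
            break
        records.append(
            EnrichmentRecord(
                sample_id=sid,
                regulator_id=seed,
                downstream_measured=down,
                n_down=len(down),
                u_statistic=u,
                p_value=p,
                rank=rank,
            )
        )
    return records


@dataclass
class SneaResult:
    """SNEA records per sample plus the regulator union for clustering."""

    per_sample: dict[str, list[EnrichmentRecord]]

    @property
    def regulators(self) -> list[str]:
        """Union of significant regulators across samples, sorted."""
        out: set[str] = set()
        for recs in self.per_sample.values():
            out.update(r.regulator_id for r in recs)
        return sorted(out)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": r.sample_id,
                "regulator": r.regulator_id,
                "n_down": r.n_down,
                "U": r.u_statistic,
                "p": r.p_value,
                "rank": r.rank,
            }
            for sid in self.per_sample
            for r in self.per_sample[sid]
        ]
        return pd.DataFrame(
            rows, columns=["sample", "regulator", "n_down", "U", "p", "rank"]
        )


def snea_all_samples(
    log_ratios: LogRatioMatrix,
    network: RegulatoryNetwork,
    config: SneaConfig | None = None,
) -> SneaResult:
    """Run SNEA independently on every disease sample."""
    config = config or SneaConfig()
    per_sample: dict[str, list[EnrichmentRecord]] = {}
    for sid in log_ratios.sample_ids:
        try:
            per_sample[sid] = snea_one_sample(
                log_ratios.values[sid], network, config, sample_id=sid
            )
        except Exception as exc:
            raise RuntimeError(f"SNEA failed for sample {sid!r}: {exc}") from exc
    return SneaResult(per_sample=per_sample)
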