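"""Naive explicit-replication Mann–Whitney oracle.

Independent of the package implementation: ranks by pairwise counting,
U by direct pair counting, and the exact conditional permutation p-value
by enumerating every subset of pooled positions (itertools for small
instances, chunked numpy for large ones).  Ties are handled through
midranks shared across the pooled multiset.
"""

from itertools import combinations, islice

import numpy as np


def _midranks(pooled: list[float]) -> list[float]:
    return [
        sum(1 for w in pooled if w < v) + (sum(1 for w in pooled if w == v) + 1) / 2.0
        for v in pooled
    ]


def oracle_mann_whitney(values_a, weights_a, values_b, weights_b,
                        alternative="two_sided"):
    """(U, p) by explicit replication and full subset enumeration."""
    a = [float(v) for v, w in zip(values_a, weights_a) for _ in range(int(w))]
    b = [float(v) for v, w in zip(values_b, weights_b) for _ in range(int(w))]
    n_a, n_b = len(a), len(b)
    u_obs = sum(
        (1.0 if x > y else 0.5 if x == y else 0.0) for x in a for y in b
    )
    pooled = a + b
    n = len(pooled)
    ranks = np.array(_midranks(pooled))
    r_obs = float(ranks[:n_a].sum())

    total = 0
    n_le = 0
    n_ge = 0
    combos = combinations(range(n), n_a)
    while True:
        chunk = list(islice(combos, 200_000))
        if not chunk:
            break
        idx = np.array(chunk, dtype=np.intp)
        sums = ranks[idx].sum(axis=1)
        total += len(chunk)
        n_le += int(np.sum(sums <= r_obs + 1e-9))
        n_ge += int(np.sum(sums >= r_obs - 1e-9))
    p_le = n_le / total
    p_ge = n_ge / total
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return u_obs, p


def random_weighted_case(rng: np.random.Generator, max_side: int = 12):
    """Random (values, weights) pair with replicated sizes <= max_side."""

    def one_side():
        target = 1 + int(max_side * rng.random() ** 2)
        weights = []
        rem = target
        while rem > 0:
            w = int(min(rem, rng.integers(1, 4)))
            weights.append(w)
            rem -= w
        if rng.random() < 0.5:
            values = rng.integers(0, 5, size=len(weights)).astype(float)  # many ties
        else:
            values = np.round(rng.normal(size=len(weights)), 2)
        return list(values), weights

    va, wa = one_side()
    vb, wb = one_side()
    alternative = rng.choice(["two_sided", "greater", "less"])
    return va, wa, vb, wb, str(alternative)
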