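from types import SimpleNamespace

import pytest

from regsubtype.activity import cluster_activity_matrix
from regsubtype.expression import compute_log_ratios, preprocess
from regsubtype.network import RegulatoryNetwork
from regsubtype.regulators import cluster_with_optimal_k, regulator_distance_matrix
from regsubtype.snea import snea_all_samples
from regsubtype.synthetic import simulate_dataset

BENCHMARK_SEED = 1


@pytest.fixture
def tiny_network() -> RegulatoryNetwork:
    return RegulatoryNetwork(
        [
            ("R1", "g1", "Expression"),
            ("R1", "g2", "Expression"),
            ("R2", "g2", "PromoterBinding"),
            ("R2", "g3", "Expression"),
        ]
    )


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark run through every pipeline stage.

    3 subtypes × 10 samples + 10 controls; 6 regulator families × 5
    regulators, 60% within-family target overlap; planted effect 2.0 on
    noise 0.3.  Shared session-wide — stages are deterministic.
    """
    ds = simulate_dataset("default", seed=BENCHMARK_SEED)
    std = preprocess(ds.expression)
    lrm = compute_log_ratios(std)
    snea = snea_all_samples(lrm, ds.network)
    dist = regulator_distance_matrix(snea.regulators, ds.network, lrm.gene_ids)
    rc = cluster_with_optimal_k(dist)
    am = cluster_activity_matrix(rc, lrm, ds.network)
    return SimpleNamespace(
        ds=ds, std=std, lrm=lrm, snea=snea, dist=dist, rc=rc, am=am
    )
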