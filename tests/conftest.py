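import numpy as np
import pytest

from funconn.connectome import BinaryGraph


def graph_from_edges(n, edges, labels=None):
    """Build a BinaryGraph from an explicit edge list."""
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    m_total = n * (n - 1) // 2
    if labels is None:
        labels = [f"n{i}" for i in range(n)]
    return BinaryGraph(adj, len(edges) / m_total, labels)


@pytest.fixture
def make_graph():
    return graph_from_edges


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny seeded cohort reused by pipeline-level tests."""
    import funconn as fc

    net = fc.PlantedNetworkSpec(n_nodes=30, n_modules=3, p_within=0.5,
                                p_between=0.05, hub_nodes=(2,), seed=7)
    cohort = fc.CohortSpec(n_per_group=(5, 5), n_timepoints=100,
                           group_effect=0.5, hub_nodes_b=(17,),
                           genotype_split=(0.6, 0.6))
    series, manifest, truth = fc.sample_cohort(net, cohort)
    return net, cohort, series, manifest, truth
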