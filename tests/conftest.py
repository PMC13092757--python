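import numpy as np
import pytest
import scipy.sparse as sp

from drpgraph.datasets import ResponseGraph, ResponseRecord, build_response_graph
from drpgraph.synthetic import generate_cohort


def finite_difference(f, params, h=1e-6):
    """Central-difference gradient of scalar f() w.r.t. each Parameter."""
    grads = []
    for p in params:
        g = np.zeros_like(p.data)
        flat = p.data.ravel()
        gflat = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + h
            fp = f()
            flat[i] = orig - h
            fm = f()
            flat[i] = orig
            gflat[i] = (fp - fm) / (2 * h)
        grads.append(g)
    return grads


def random_multirelation_graph(rng, n_nodes, n_relations, edge_prob=0.3,
                               f_dim=4) -> ResponseGraph:
    """A small directed multigraph with random relation adjacencies."""
    n_cells = max(1, n_nodes // 2)
    relations = {}
    names = ["sensitive", "resistant", "cell_sim"][:n_relations]
    for name in names:
        a = (rng.random((n_nodes, n_nodes)) < edge_prob).astype(float)
        np.fill_diagonal(a, 0.0)
        relations[name] = sp.csr_matrix(a)
    g = ResponseGraph(cell_ids=[f"c{i}" for i in range(n_cells)],
                      drug_ids=[f"d{i}" for i in range(n_nodes - n_cells)],
                      relations=relations)
    g.features = rng.standard_normal((n_nodes, f_dim))
    return g


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort reused by pipeline-level tests."""
    return generate_cohort(n_cells=30, n_drugs=20, k_latent=4, noise_sd=0.3,
                           target_prevalence=0.1, seed=7)


@pytest.fixture
def tiny_graph():
    """4 cells x 3 drugs, 2 sensitive + 2 resistant edges."""
    records = [
        ResponseRecord("c0", "d0", -4.0, "sensitive"),
        ResponseRecord("c1", "d0", -5.0, "sensitive"),
        ResponseRecord("c2", "d1", 4.0, "resistant"),
        ResponseRecord("c3", "d2", 5.0, "resistant"),
    ]
    return build_response_graph([f"c{i}" for i in range(4)],
                                [f"d{i}" for i in range(3)], records)
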