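import numpy as np
import pytest

import alloscan as al


@pytest.fixture(scope="session")
def small_states():
    """Three noise-bearing reference states on a short chain."""
    return al.generate_reference_states(
        n_residues=80, loop_span=(30, 45), n_models=10, noise_sd=0.3, seed=42
    )


@pytest.fixture(scope="session")
def small_refs(small_states):
    return {label: s.ensemble for label, s in small_states.items()}


@pytest.fixture(scope="session")
def planted_bridge_spec():
    return al.PlantedNetworkSpec(
        community_sizes=[12, 12],
        bridge_nodes=[5],
        intra_corr=0.5,
        inter_corr=0.0,
        bridge_corr=0.3,
    )


@pytest.fixture(scope="session")
def planted_bridge_network(planted_bridge_spec):
    """Network built end-to-end from the planted single-bridge ensemble."""
    ens = al.generate_correlated_ensemble(planted_bridge_spec, n_models=300, seed=9)
    persistence = al.contact_persistence(ens, cutoff=5.0, min_fraction=0.75)
    gc = al.gc_matrix(ens, estimator="gaussian", superpose=False)
    return al.build_network(persistence, gc)


def make_toy_network(edges, n_nodes=None):
    """Residue interaction network from an explicit weighted edge list.

    ``edges`` is a list of (u, v, weight) with 1-based node ids.
    """
    import networkx as nx

    g = nx.Graph()
    nodes = sorted({u for u, v, _ in edges} | {v for u, v, _ in edges})
    if n_nodes is not None:
        nodes = sorted(set(nodes) | set(range(1, n_nodes + 1)))
    g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w))
    ids = np.array(nodes)
    gc = al.CorrelationMatrix(ids, np.eye(ids.size), "gc")
    return al.ResidueInteractionNetwork(graph=g, gc=gc)
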