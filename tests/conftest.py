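import numpy as np
import pandas as pd
import pytest

import wmnet as w


@pytest.fixture(scope="session")
def straight_phantom():
    """Noiseless straight-bundle phantom with its fitted field and tracks."""
    spec = w.straight_bundle_spec(length=16, fa=0.8, noise_sd=0.0, seed=1)
    phantom = w.generate_phantom(spec)
    field = phantom.fit()
    streamlines = w.track_fact(field)
    return phantom, field, streamlines


@pytest.fixture(scope="session")
def bent_phantom():
    spec = w.bent_bundle_spec(arm=10, fa=0.8, noise_sd=0.0, seed=1)
    phantom = w.generate_phantom(spec)
    field = phantom.fit()
    streamlines = w.track_fact(field)
    return phantom, field, streamlines


@pytest.fixture(scope="session")
def small_cohort():
    """A 6+8-subject cohort with 30-node connectomes, no planted effects."""
    table = w.generate_cohort(w.CohortSpec(n_is=6, n_nis=8, seed=11))
    conns = w.generate_connectomes(table, n_nodes=30, seed=12)
    return table, conns


def binary_graph_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return w.BinaryGraph(adj, sparsity=2 * len(edges) / (n * (n - 1)))


@pytest.fixture(scope="session")
def k4():
    return binary_graph_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])


@pytest.fixture(scope="session")
def cycle5():
    return binary_graph_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)])


@pytest.fixture(scope="session")
def star5():
    """Node 0 is the hub."""
    return binary_graph_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])


@pytest.fixture(scope="session")
def path3():
    return binary_graph_from_edges(3, [(0, 1), (1, 2)])


def phantom_label_volume(phantom):
    ids = sorted(int(v) for v in np.unique(phantom.labels) if v > 0)
    nodes = pd.DataFrame(
        {"index": ids, "abbrev": [f"ROI{v}" for v in ids], "hemisphere": "L"}
    )
    return w.LabelVolume(phantom.labels, nodes)
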