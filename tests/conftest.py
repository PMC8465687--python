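import numpy as np
import pytest

from graphgranger import Graph, GraphSeries, ModelSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_er_series(n: int, T: int, p: float, seed: int, label: str = "") -> GraphSeries:
    graphs = tuple(generate(ModelSpec("erdos_renyi", n, p), seed + t) for t in range(T))
    return GraphSeries(graphs, label=label)


def graph_from_edges(n: int, edges, weights=None) -> Graph:
    a = np.zeros((n, n))
    for idx, (u, v) in enumerate(edges):
        w = 1.0 if weights is None else weights[idx]
        a[u, v] = a[v, u] = w
    return Graph(a)
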