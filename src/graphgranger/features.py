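"""Scalar graph features: spectral radius and centrality summaries.

The spectral radius — the largest eigenvalue of the (symmetric) adjacency
matrix — is the primary feature: for several random-graph families it is a
known function of the generating parameter, so its time series tracks the
latent parameter process.  Centrality-based alternatives (mean betweenness,
closeness, eigenvector and degree centrality) are provided for comparison.

Per-vertex centralities are reduced to one scalar per graph by averaging
over vertices.  Betweenness is the unnormalized shortest-path count;
closeness is harmonic closeness, which stays finite on disconnected graphs;
eigenvector centrality is the unit-norm principal eigenvector (entries
nonnegative by Perron–Frobenius, sign fixed accordingly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import scipy.sparse.linalg

from .exceptions import ParameterError, ValidationError
from .graphmodels import Graph

FEATURES = ("spectral_radius", "betweenness", "closeness", "eigenvector", "degree")

#: above this vertex count a Lanczos solve for the top eigenvalue is cheaper
#: than a full symmetric eigen-decomposition
_LANCZOS_THRESHOLD = 150


@dataclass(frozen=True)
class FeatureSeries:
    """A T x k matrix of per-time-point graph features.

    Column ``i`` holds the feature of the ``i``-th graph series at each time
    point.  Also used for the latent parameter processes of the simulation
    scenarios (where the "feature" is the latent value itself).
    """

    values: np.ndarray
    labels: tuple[str, ...] = ()
    feature_name: str = "spectral_radius"

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.ndim != 2:
            raise ValidationError(f"values must be 2-d (T x k), got shape {v.shape}")
        if v.shape[0] < 2:
            raise ValidationError(f"need at least 2 time points, got {v.shape[0]}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("feature series contains non-finite values")
        labels = tuple(self.labels) if self.labels else tuple(f"y{i+1}" for i in range(v.shape[1]))
        if len(labels) != v.shape[1]:
            raise ValidationError(f"{len(labels)} labels for {v.shape[1]} series")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", labels)

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def spectral_radius(g: Graph) -> float:
    """Largest eigenvalue of the adjacency matrix (lambda_1, not max |lambda|)."""
    a = g.adjacency
    n = a.shape[0]
    if n == 1:
        return 0.0
    if n > _LANCZOS_THRESHOLD:
        try:
            return float(
                scipy.sparse.linalg.eigsh(a, k=1, which="LA", return_eigenvectors=False)[0]
            )
        except scipy.sparse.linalg.ArpackNoConvergence:  # pragma: no cover - rare
            pass
    return float(np.linalg.eigvalsh(a)[-1])


def _to_networkx(g: Graph) -> nx.Graph:
    return nx.from_numpy_array(g.adjacency)


def centrality_feature(g: Graph, name: str) -> float:
    """Graph-level summary of a per-vertex centrality: the mean over vertices."""
    n = g.n_vertices
    if name == "spectral_radius":
        return spectral_radius(g)
    if name == "degree":
        return float(np.mean(g.degrees()))
    if name == "betweenness":
        bc = nx.betweenness_centrality(_to_networkx(g), normalized=False)
        return float(np.mean(list(bc.values())))
    if name == "closeness":
        # harmonic closeness: finite on disconnected graphs
        hc = nx.harmonic_centrality(_to_networkx(g))
        return float(np.mean(list(hc.values())))
    if name == "eigenvector":
        vals, vecs = np.linalg.eigh(g.adjacency)
        v = vecs[:, -1]
        if v.sum() < 0:
            v = -v
        return float(np.mean(v))
    raise ParameterError(f"unknown feature {name!r}; expected one of {FEATURES}")


def graph_feature(g: Graph, name: str) -> float:
    """Dispatch: spectral radius or a centrality summary."""
    if name not in FEATURES:
        raise ParameterError(f"unknown feature {name!r}; expected one of {FEATURES}")
    return centrality_feature(g, name)


def extract_series(series: Sequence, feature: str = "spectral_radius") -> FeatureSeries:
    """Reduce each graph series to a scalar time series of the chosen feature.

    ``series`` is a sequence of :class:`~graphgranger.pipeline.GraphSeries`
    (anything exposing ``.graphs`` and ``.label``); all must share the same
    length T.  Returns the T x k feature matrix.
    """
    if len(series) == 0:
        raise ValidationError("no graph series given")
    lengths = {len(s.graphs) for s in series}
    if len(lengths) != 1:
        raise ValidationError(f"graph series have unequal lengths: {sorted(lengths)}")
    (T,) = lengths
    if T < 2:
        raise ValidationError(f"graph series too short (T={T})")
    cols = [np.array([graph_feature(g, feature) for g in s.graphs]) for s in series]
    labels = tuple(getattr(s, "label", None) or f"y{i+1}" for i, s in enumerate(series))
    return FeatureSeries(np.column_stack(cols), labels, feature_name=feature)
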