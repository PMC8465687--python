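"""Time-varying correlation graphs from multivariate signals.

Given a T x n signal matrix (e.g. mean BOLD time series of brain regions),
this module builds one weighted graph per time point whose edge weights are
time-varying Pearson correlations.  The estimator is spline-based:

1. a cubic regression-spline trend is removed from each channel;
2. the instantaneous cross-products of the centered channels are smoothed
   with the same spline basis, giving time-varying covariance and variance
   estimates;
3. the correlation r_ab(t) = cov_ab(t) / sqrt(var_a(t) var_b(t)) is clipped
   to [-1, 1].

The single smoothing knob is the basis dimension ``df`` (number of B-spline
basis functions, default T // 10, at least 4).  With ``df = 1`` the basis
degenerates to a constant and r(t) collapses to the ordinary static Pearson
correlation.  Smoothed squares can undershoot zero, so variances are floored
at a small epsilon before division; edges whose variance hits the floor get
weight 0.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import BSpline

from .exceptions import ParameterError, ValidationError
from .graphmodels import Graph
from .pipeline import GraphSeries

_VAR_EPS = 1e-10


def _spline_basis(T: int, df: int) -> np.ndarray:
    """T x df cubic B-spline design matrix on an evenly spaced grid."""
    if df == 1:
        return np.ones((T, 1))
    if df < 4:
        raise ParameterError(f"df must be 1 (constant) or >= 4 (cubic basis), got {df}")
    if df >= T:
        raise ParameterError(f"df={df} must be smaller than the series length T={T}")
    x = np.linspace(0.0, 1.0, T)
    degree = 3
    n_interior = df - degree - 1
    interior = np.linspace(0, 1, n_interior + 2)[1:-1]
    knots = np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])
    return BSpline.design_matrix(x, knots, degree).toarray()


def _smooth(basis: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares projection of each column of y onto the spline basis."""
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return basis @ coef


def time_varying_correlation(
    signals: np.ndarray,
    labels: Sequence[str] | None = None,
    df: int | None = None,
    label: str = "",
) -> GraphSeries:
    """Weighted correlation-graph series from a T x n signal matrix."""
    x = np.asarray(signals, dtype=float)
    if x.ndim != 2:
        raise ValidationError(f"signals must be a T x n matrix, got shape {x.shape}")
    T, n = x.shape
    if T < 10:
        raise ValidationError(f"need at least 10 time points, got {T}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("signal matrix contains non-finite values")
    if df is None:
        df = max(4, T // 10)
    basis = _spline_basis(T, df)

    centered = x - _smooth(basis, x)
    # all pairwise products (upper triangle) plus squares, smoothed in one solve
    iu, ju = np.triu_indices(n, k=1)
    prods = np.concatenate([centered**2, centered[:, iu] * centered[:, ju]], axis=1)
    smoothed = _smooth(basis, prods)
    var = smoothed[:, :n]
    cov = smoothed[:, n:]

    floored = var < _VAR_EPS
    if np.any(floored):
        warnings.warn(
            f"{int(floored.sum())} smoothed variance value(s) at or below zero; "
            "affected edge weights set to 0",
            stacklevel=2,
        )
    var_safe = np.maximum(var, _VAR_EPS)
    denom = np.sqrt(var_safe[:, iu] * var_safe[:, ju])
    r = np.clip(cov / denom, -1.0, 1.0)
    r[floored[:, iu] | floored[:, ju]] = 0.0

    graphs = []
    for t in range(T):
        a = np.zeros((n, n))
        a[iu, ju] = r[t]
        a[ju, iu] = r[t]
        graphs.append(Graph(a))
    return GraphSeries(tuple(graphs), label=label, weighted=True)


def split_subnetworks(
    gs: GraphSeries, membership: Sequence[str] | Mapping[int, str]
) -> dict[str, GraphSeries]:
    """Split a graph series into induced-subgraph series, one per group label.

    ``membership`` assigns a group label to every vertex (a length-n sequence
    or a {vertex: label} mapping covering all vertices).  Vertex order within
    each group follows the original ordering.
    """
    n = gs.n_vertices
    if isinstance(membership, Mapping):
        try:
            labels = [membership[i] for i in range(n)]
        except KeyError as exc:
            raise ValidationError(f"membership missing vertex {exc.args[0]}")
    else:
        labels = list(membership)
        if len(labels) != n:
            raise ValidationError(f"membership has {len(labels)} entries for {n} vertices")
    groups: dict[str, list[int]] = {}
    for v, lab in enumerate(labels):
        groups.setdefault(str(lab), []).append(v)
    out = {}
    for lab, verts in groups.items():
        if len(verts) < 1:
            raise ValidationError(f"group {lab!r} is empty")
        idx = np.asarray(verts)
        graphs = tuple(Graph(g.adjacency[np.ix_(idx, idx)]) for g in gs.graphs)
        out[lab] = GraphSeries(graphs, label=lab or gs.label, weighted=gs.weighted)
    return out
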