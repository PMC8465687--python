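"""End-to-end workflow: graph time series in, causality results out.

``graph_granger`` chains the stages: extract one scalar feature per graph
(default: spectral radius), optionally select the VAR order by AIC, fit the
VAR by OLS, and test Granger non-causality for every ordered pair of series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from . import features as _features
from . import gctest as _gctest
from . import var as _var
from .exceptions import ParameterError, ValidationError
from .graphmodels import Graph


@dataclass(frozen=True)
class GraphSeries:
    """An ordered sequence of graphs on a fixed vertex set — one network
    observed at T time points."""

    graphs: tuple[Graph, ...]
    label: str = ""
    weighted: bool = False

    def __post_init__(self):
        graphs = tuple(self.graphs)
        if len(graphs) < 2:
            raise ValidationError(f"a graph series needs T >= 2 time points, got {len(graphs)}")
        sizes = {g.n_vertices for g in graphs}
        if len(sizes) != 1:
            raise ValidationError(f"all graphs in a series must share n_vertices, got {sorted(sizes)}")
        object.__setattr__(self, "graphs", graphs)

    @property
    def T(self) -> int:
        return len(self.graphs)

    @property
    def n_vertices(self) -> int:
        return self.graphs[0].n_vertices

    def empty_time_points(self) -> list[int]:
        """Indices of graphs with no edges (spectral radius identically 0)."""
        return [t for t, g in enumerate(self.graphs) if g.n_edges == 0]


def graph_granger(
    series: Sequence[GraphSeries],
    feature: str = "spectral_radius",
    order: int | str = "auto",
    method: str = "wald",
    n_boot: int = 1000,
    seed: int = 0,
    sigma_df: str = "intercept",
    allow_empty: bool = False,
    p_max: int | None = None,
) -> tuple[Mapping[tuple[int, int], _gctest.GCTestResult], _var.VARModel]:
    """Test Granger causality between every ordered pair of graph series.

    Parameters
    ----------
    series:
        Two or more graph series of equal length T (vertex counts may differ
        between series).
    feature:
        Scalar graph feature; ``"spectral_radius"`` (default) or one of the
        centrality summaries.
    order:
        VAR order p, or ``"auto"`` to select by AIC with
        p_max = min(10, (T-1) // (k+1)) unless ``p_max`` is given.
    method:
        ``"wald"`` (asymptotic chi-squared) or ``"bootstrap"``.
    allow_empty:
        Graphs with an empty edge set violate the model's assumption of
        non-empty graphs.  By default they raise; with ``allow_empty=True``
        their feature value (0 for the spectral radius) is used and a
        warning emitted.

    Returns
    -------
    (results, model):
        The per-pair test results and the fitted VAR for inspection.
    """
    if len(series) < 2:
        raise ValidationError("need at least two graph series")
    for s in series:
        empties = s.empty_time_points()
        if empties:
            msg = (
                f"series {s.label or series.index(s)} has empty graphs at time "
                f"points {empties[:5]}{'...' if len(empties) > 5 else ''}"
            )
            if not allow_empty:
                raise ValidationError(msg + " (pass allow_empty=True to proceed)")
            warnings.warn(msg + "; using feature value of the empty graph", stacklevel=2)

    y = _features.extract_series(series, feature)
    k, T = y.k, y.T
    if order == "auto":
        cap = p_max if p_max is not None else min(10, (T - 1) // (k + 1))
        if cap < 1:
            raise ParameterError(f"series too short to select an order (T={T}, k={k})")
        p = _var.select_order(y, cap, sigma_df=sigma_df)
    else:
        p = int(order)
    model = _var.fit(y, p, sigma_df=sigma_df)
    results = _gctest.test_all_pairs(
        y, p, method=method, n_boot=n_boot, seed=seed, sigma_df=sigma_df
    )
    return results, model
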