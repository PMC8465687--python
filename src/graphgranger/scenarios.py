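"""Simulation scenarios: latent VAR processes driving random-graph series.

Five benchmark scenarios define latent linear processes with known causal
structure (coefficients +-0.5, Gaussian errors with unit variance and 0.1
cross-covariance):

1. two independent AR(1) series (the null case);
2. a direct effect y1 -> y2;
3. one driver, two targets (y1 -> y2, y1 -> y3);
4. direct and indirect effects (y1 -> y2 -> y3, y1 -> y3 at lag 2, y3 -> y4);
5. a feedback loop (y1 -> y2 -> y3 -> y4 -> y2).

Each latent value is squashed to (0, 1) by the inverse logit and interpreted
as the parameter of a random-graph family: Erdős–Rényi edge probability,
geometric radius, regular degree (floor of 10x), Watts–Strogatz rewiring
probability, or Barabási–Albert attachment power (2x).  Generating one graph
per time point yields graph series whose spectral-radius dynamics inherit
the latent causal structure — the ground truth against which type-I error
and power of the causality tests are measured.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.special

from . import features as _features
from . import gctest as _gctest
from .exceptions import ParameterError
from .features import FeatureSeries
from .graphmodels import ModelSpec, generate
from .pipeline import GraphSeries


@dataclass(frozen=True)
class ScenarioSpec:
    """A latent VAR data-generating process with known causal edges.

    ``coefficients`` holds (source, target, lag, value) with 0-based series
    indices; ``causal_pairs`` lists the true directed causal relations
    implied by the cross coefficients.
    """

    id: int
    k: int
    coefficients: tuple[tuple[int, int, int, float], ...]

    @property
    def max_lag(self) -> int:
        return max(c[2] for c in self.coefficients)

    @property
    def causal_pairs(self) -> set[tuple[int, int]]:
        return {(s, t) for s, t, _, _ in self.coefficients if s != t}

    def error_covariance(self) -> np.ndarray:
        cov = np.full((self.k, self.k), 0.1)
        np.fill_diagonal(cov, 1.0)
        return cov


SCENARIOS: dict[int, ScenarioSpec] = {
    1: ScenarioSpec(1, 2, ((0, 0, 1, 0.5), (1, 1, 1, 0.5))),
    2: ScenarioSpec(2, 2, ((0, 0, 1, 0.5), (0, 1, 1, 0.5))),
    3: ScenarioSpec(3, 3, ((0, 1, 1, 0.5), (0, 2, 1, -0.5))),
    4: ScenarioSpec(4, 4, ((0, 1, 1, 0.5), (0, 2, 2, -0.5), (1, 2, 1, 0.5), (2, 3, 1, 0.5))),
    5: ScenarioSpec(5, 4, ((0, 1, 1, 0.5), (3, 1, 1, -0.5), (1, 2, 2, -0.5), (2, 3, 1, 0.5))),
}

#: per-family constants used throughout the simulation study
DEFAULT_NEI = 3
DEFAULT_M1 = 1

_BURN_IN = 50


def get_scenario(scenario: int | ScenarioSpec) -> ScenarioSpec:
    if isinstance(scenario, ScenarioSpec):
        return scenario
    try:
        return SCENARIOS[int(scenario)]
    except (KeyError, ValueError):
        raise ParameterError(f"unknown scenario {scenario!r}; expected 1..5")


def inverse_logit(x):
    """1 / (1 + exp(-x)), mapping the real line to (0, 1)."""
    return scipy.special.expit(x)


def simulate_latent(
    scenario: int | ScenarioSpec,
    T: int,
    seed: int | np.random.SeedSequence = 0,
    burn_in: int = _BURN_IN,
    error_cov: np.ndarray | None = None,
    return_errors: bool = False,
):
    """Simulate the latent linear process of a scenario.

    The recursion starts at zero and runs ``burn_in`` extra steps that are
    discarded, so the retained T points are effectively stationary.  Errors
    are multivariate normal with the scenario covariance unless
    ``error_cov`` overrides it (e.g. zeros for a noise-free check).

    Returns a :class:`FeatureSeries` (T x k); with ``return_errors=True``,
    a (series, errors) pair where ``errors`` are the T injected error rows.
    """
    spec = get_scenario(scenario)
    if T < 10:
        raise ParameterError(f"T must be >= 10, got {T}")
    k, p = spec.k, spec.max_lag
    cov = spec.error_covariance() if error_cov is None else np.asarray(error_cov, float)
    rng = np.random.default_rng(seed)
    total = T + burn_in
    if np.any(cov):
        L = np.linalg.cholesky(cov)
        eps = rng.standard_normal((total, k)) @ L.T
    else:
        eps = np.zeros((total, k))
    y = np.zeros((total + p, k))
    for t in range(p, total + p):
        row = eps[t - p].copy()
        for s, tgt, lag, val in spec.coefficients:
            row[tgt] += val * y[t - lag, s]
        y[t] = row
    out = FeatureSeries(y[p + burn_in :], feature_name="latent")
    if return_errors:
        return out, eps[burn_in:]
    return out


def _family_spec(family: str, s: float, n: int, nei: int, m1: int) -> ModelSpec:
    """Map an inverse-logit value s in (0,1) to a graph-model parameter."""
    if family == "regular":
        return ModelSpec(family, n, float(math.floor(10.0 * s)), nei=nei, m1=m1)
    if family == "barabasi_albert":
        return ModelSpec(family, n, 2.0 * s, nei=nei, m1=m1)
    # erdos_renyi p, geometric r, watts_strogatz pw: the value itself
    return ModelSpec(family, n, float(s), nei=nei, m1=m1)


def to_graph_series(
    latent: FeatureSeries,
    family: str,
    n: int,
    seed: int = 0,
    nei: int = DEFAULT_NEI,
    m1: int = DEFAULT_M1,
    redraw_empty: bool = False,
    max_redraws: int = 20,
) -> list[GraphSeries]:
    """Turn latent series into graph series, one independent graph per point.

    Each latent value is squashed by the inverse logit and used as the
    family parameter.  Graph randomness is derived from ``seed`` with a
    separate substream per (series, time point).  Regular graphs with
    deg = 0 have no edges; by default they are kept with a warning (their
    spectral radius is 0), or re-drawn from fresh substreams when
    ``redraw_empty`` is set (only useful for families where a redraw can
    actually produce edges).
    """
    s_vals = inverse_logit(latent.values)
    T, k = s_vals.shape
    out = []
    n_empty = 0
    for j in range(k):
        graphs = []
        for t in range(T):
            spec = _family_spec(family, s_vals[t, j], n, nei, m1)
            for attempt in range(max_redraws + 1):
                gseed = int(
                    np.random.SeedSequence([int(seed), j, t, attempt]).generate_state(1)[0]
                    % (2**31)
                )
                g = generate(spec, gseed)
                if g.n_edges > 0 or not redraw_empty:
                    break
            if g.n_edges == 0:
                n_empty += 1
            graphs.append(g)
        out.append(GraphSeries(tuple(graphs), label=latent.labels[j]))
    if n_empty:
        warnings.warn(
            f"{n_empty} generated graph(s) have no edges (spectral radius 0)",
            stacklevel=2,
        )
    return out


def collect_pvalues(
    scenario: int | ScenarioSpec,
    family: str,
    n: int,
    T: int,
    reps: int,
    method: str = "wald",
    feature: str = "spectral_radius",
    seed: int = 0,
    order: int | None = None,
    n_boot: int = 1000,
    nei: int = DEFAULT_NEI,
    m1: int = DEFAULT_M1,
) -> pd.DataFrame:
    """Per-replicate p-values for every directed pair of one scenario cell.

    Each replicate simulates the latent process, generates graph series,
    extracts the feature, fits a VAR (order defaults to the scenario's true
    maximum lag) and tests every ordered pair.  Replicates whose fit fails
    (singular design) are skipped.  Returns one row per (replicate, pair).
    """
    spec = get_scenario(scenario)
    if reps < 1:
        raise ParameterError(f"reps must be >= 1, got {reps}")
    p = spec.max_lag if order is None else int(order)
    rows = []
    for rep in range(reps):
        latent_ss = np.random.SeedSequence([int(seed), rep, 0])
        graph_seed = int(np.random.SeedSequence([int(seed), rep, 1]).generate_state(1)[0] % 2**31)
        latent = simulate_latent(spec, T, seed=latent_ss)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series = to_graph_series(latent, family, n, seed=graph_seed, nei=nei, m1=m1)
            try:
                y = _features.extract_series(series, feature)
                results = _gctest.test_all_pairs(
                    y, p, method=method, n_boot=n_boot,
                    seed=int(
                        np.random.SeedSequence([int(seed), rep, 2]).generate_state(1)[0] % 2**31
                    ),
                )
            except Exception:
                continue
        for (i, j), res in results.items():
            rows.append(
                {"replicate": rep, "source": i + 1, "target": j + 1,
                 "causal": (i, j) in spec.causal_pairs, "p_value": res.p_value}
            )
    if not rows:
        raise RuntimeError("every replicate failed; check the configuration")
    return pd.DataFrame(rows)


def run_experiment(
    scenario: int | ScenarioSpec,
    family: str,
    n: int,
    T: int,
    reps: int = 1000,
    method: str = "wald",
    alpha: float = 0.05,
    feature: str = "spectral_radius",
    seed: int = 0,
    order: int | None = None,
    n_boot: int = 1000,
    nei: int = DEFAULT_NEI,
    m1: int = DEFAULT_M1,
) -> pd.DataFrame:
    """Monte-Carlo rejection rates for one (scenario, family, n, T) cell.

    The fraction of replicates with p-value below ``alpha``, per directed
    pair, over the replicates produced by :func:`collect_pvalues`.
    """
    spec = get_scenario(scenario)
    pvals = collect_pvalues(
        spec, family, n, T, reps, method=method, feature=feature, seed=seed,
        order=order, n_boot=n_boot, nei=nei, m1=m1,
    )
    grouped = pvals.groupby(["source", "target"], sort=True)
    rows = [
        {
            "scenario": spec.id,
            "family": family,
            "n": n,
            "T": T,
            "source": src,
            "target": tgt,
            "causal": bool(sub["causal"].iloc[0]),
            "rejection_rate": float((sub["p_value"] < alpha).mean()),
            "reps_effective": int(len(sub)),
        }
        for (src, tgt), sub in grouped
    ]
    return pd.DataFrame(rows)


def run_grid(
    scenario: int | ScenarioSpec,
    family: str,
    n_list: Sequence[int],
    T_list: Sequence[int],
    reps: int,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Rejection rates over an (n, T) grid — one row block per cell."""
    frames = []
    for a, n in enumerate(n_list):
        for b, T in enumerate(T_list):
            cell_seed = int(
                np.random.SeedSequence([int(seed), a, b]).generate_state(1)[0] % 2**31
            )
            frames.append(
                run_experiment(scenario, family, n, T, reps=reps, seed=cell_seed, **kwargs)
            )
    return pd.concat(frames, ignore_index=True)


def rejection_heatmap(table: pd.DataFrame, source: int, target: int, ax=None):
    """Heatmap of rejection rate over the (n, T) grid for one directed pair."""
    import matplotlib.pyplot as plt

    sub = table[(table["source"] == source) & (table["target"] == target)]
    pivot = sub.pivot_table(index="n", columns="T", values="rejection_rate")
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(pivot.values, cmap="RdYlGn", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns)
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    ax.set_xlabel("T")
    ax.set_ylabel("n")
    ax.set_title(f"rejection rate {source} → {target}")
    for (r, c), val in np.ndenumerate(pivot.values):
        ax.text(c, r, f"{val:.2f}", ha="center", va="center", fontsize=8)
    ax.figure.colorbar(im, ax=ax)
    return ax
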