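"""Random-graph generators and their known spectral-radius laws.

Five classical families are supported: Erdős–Rényi, random geometric,
random regular, Watts–Strogatz and Barabási–Albert.  Each family has a single
driving parameter (edge probability ``p``, neighborhood radius ``r``, degree
``deg``, rewiring probability ``pw``, preferential-attachment power ``ps``)
plus family-specific constants (``nei`` for Watts–Strogatz, ``m1`` for
Barabási–Albert).  For several of these families the spectral radius of the
adjacency matrix is a known (exact or asymptotic) function of the parameter —
e.g. ``n*p`` for Erdős–Rényi, ``deg`` for a regular graph — which is what
makes the spectral radius a useful observable proxy for the latent parameter.

Generation is deterministic: ``generate(spec, seed)`` is a pure function of
its arguments.  The nontrivial constructions delegate to python-igraph
(seeded with a dedicated ``random.Random`` instance); the Erdős–Rényi model
is drawn directly as a Bernoulli upper triangle with numpy, which is exact
and considerably faster for the Monte-Carlo studies this package runs.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np

from .exceptions import ConstructionError, ParameterError, ValidationError

FAMILIES = ("erdos_renyi", "geometric", "regular", "watts_strogatz", "barabasi_albert")


@dataclass(frozen=True)
class Graph:
    """An undirected graph stored as a dense symmetric adjacency matrix.

    Entries are 0/1 for simple graphs and arbitrary reals for weighted
    graphs (e.g. correlation networks).  The diagonal is always zero.
    """

    adjacency: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] < 1:
            raise ValidationError(f"adjacency must be square and non-empty, got shape {a.shape}")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValidationError("adjacency matrix must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValidationError("adjacency diagonal must be zero (no self-loops)")
        object.__setattr__(self, "adjacency", a)

    @property
    def n_vertices(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of (undirected) edges with nonzero weight."""
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.adjacency, (0.0, 1.0)).all())

    def degrees(self) -> np.ndarray:
        """Vertex degrees (weighted graphs: number of incident nonzero edges)."""
        return np.count_nonzero(self.adjacency, axis=1)


@dataclass(frozen=True)
class ModelSpec:
    """A random-graph family together with its parameters.

    ``param`` is the family's driving parameter: ``p`` (erdos_renyi),
    ``r`` (geometric), ``deg`` (regular), ``pw`` (watts_strogatz) or
    ``ps`` (barabasi_albert).  ``nei`` is the per-side neighbor count of the
    Watts–Strogatz ring lattice; ``m1`` the number of edges each new vertex
    brings in the Barabási–Albert construction.
    """

    family: str
    n: int
    param: float
    nei: int = 3
    m1: int = 1

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.n < 1:
            raise ParameterError(f"n must be >= 1, got {self.n}")
        fam, x = self.family, self.param
        if fam == "erdos_renyi" and not 0.0 <= x <= 1.0:
            raise ParameterError(f"edge probability p must be in [0, 1], got {x}")
        if fam == "geometric" and x < 0:
            raise ParameterError(f"radius r must be >= 0, got {x}")
        if fam == "regular":
            if x != int(x) or not 0 <= x <= self.n - 1:
                raise ParameterError(f"degree must be an integer in [0, n-1], got {x}")
        if fam == "watts_strogatz" and not 0.0 <= x <= 1.0:
            raise ParameterError(f"rewiring probability pw must be in [0, 1], got {x}")
        if fam == "barabasi_albert" and x < 0:
            raise ParameterError(f"attachment power ps must be >= 0, got {x}")
        if self.nei < 1:
            raise ParameterError(f"nei must be >= 1, got {self.nei}")
        if self.m1 < 1:
            raise ParameterError(f"m1 must be >= 1, got {self.m1}")


def _adjacency_from_igraph(g: ig.Graph, n: int) -> np.ndarray:
    a = np.zeros((n, n))
    edges = np.asarray(g.get_edgelist(), dtype=int)
    if edges.size:
        a[edges[:, 0], edges[:, 1]] = 1.0
        a[edges[:, 1], edges[:, 0]] = 1.0
    return a


def generate(spec: ModelSpec, seed: int) -> Graph:
    """Draw one simple undirected graph from the family in ``spec``.

    The same ``(spec, seed)`` pair always reproduces the identical graph.
    """
    fam, n = spec.family, spec.n

    if fam == "erdos_renyi":
        rng = np.random.default_rng(seed)
        upper = np.triu(rng.random((n, n)) < spec.param, k=1).astype(float)
        return Graph(upper + upper.T)

    # remaining families: igraph constructions with a private seeded RNG
    ig.set_random_number_generator(random.Random(int(seed)))
    try:
        if fam == "geometric":
            g = ig.Graph.GRG(n, float(spec.param), torus=False)
        elif fam == "regular":
            deg = int(spec.param)
            if (n * deg) % 2 == 1:
                warnings.warn(
                    f"regular graph with n={n}, deg={deg} infeasible (odd n*deg); "
                    f"using deg={deg - 1}",
                    stacklevel=2,
                )
                deg -= 1
            try:
                g = ig.Graph.K_Regular(n, deg)
            except ig.InternalError as exc:  # pragma: no cover - igraph rarely fails here
                raise ConstructionError(f"cannot build {deg}-regular graph on {n} vertices: {exc}")
        elif fam == "watts_strogatz":
            g = ig.Graph.Watts_Strogatz(1, n, spec.nei, float(spec.param), loops=False, multiple=False)
        elif fam == "barabasi_albert":
            g = ig.Graph.Barabasi(n, m=spec.m1, power=float(spec.param), directed=False)
        else:  # pragma: no cover
            raise ParameterError(f"unknown family {fam!r}")
    finally:
        ig.set_random_number_generator(random)  # restore igraph's default source
    g.simplify()
    return Graph(_adjacency_from_igraph(g, n))


@dataclass(frozen=True)
class SpectralRadiusLaw:
    """Closed-form or asymptotic spectral radius implied by a model spec.

    ``value`` is ``None`` when no analytic expression is known
    (Watts–Strogatz).  ``asymptotic`` marks large-``n`` limit laws that are
    not exact at finite ``n`` (geometric, Barabási–Albert).
    """

    value: float | None
    asymptotic: bool = False
    defined: bool = True


def theoretical_spectral_radius(spec: ModelSpec) -> SpectralRadiusLaw:
    """Known spectral-radius law for the family, where one exists.

    Erdős–Rényi: ``n*p`` (concentration of the largest eigenvalue).
    Regular: exactly ``deg`` (the all-ones vector is an eigenvector).
    Geometric: the large-``n`` almost-sure limit ``r * d`` on the unit square
    (``d`` = 2), reported with the asymptotic flag.
    Barabási–Albert: order ``sqrt(k0) * n**((ps - 1) / 2)`` with the smallest
    degree ``k0`` taken as ``m1``; asymptotic order-of-magnitude only.
    Watts–Strogatz: no analytic expression is known; ``defined`` is False.
    """
    fam = spec.family
    if fam == "erdos_renyi":
        return SpectralRadiusLaw(spec.n * spec.param)
    if fam == "regular":
        return SpectralRadiusLaw(float(int(spec.param)))
    if fam == "geometric":
        return SpectralRadiusLaw(spec.param * 2.0, asymptotic=True)
    if fam == "barabasi_albert":
        k0 = float(spec.m1)
        return SpectralRadiusLaw(
            np.sqrt(k0) * spec.n ** (0.5 * (spec.param - 1.0)), asymptotic=True
        )
    return SpectralRadiusLaw(None, defined=False)
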