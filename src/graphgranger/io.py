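"""Readers and writers for the on-disk formats.

Graph series live in a directory per series: zero-padded, t-indexed edge
list files (``0001.tsv`` ...) with a ``u<TAB>v[<TAB>weight]`` header and
0-based vertex ids, plus a ``meta.json`` sidecar recording ``n_vertices``,
``T``, ``weighted`` and the series label.  Dense whitespace-delimited
adjacency text and GraphML (read-only) are also accepted for single graphs.
Feature series are TSV with one row per time point and the series labels as
header.  All writer/reader pairs round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError
from .features import FeatureSeries
from .gctest import GCTestResult
from .graphmodels import Graph
from .pipeline import GraphSeries
from .var import VARModel

# ---------------------------------------------------------------------------
# graphs and graph series


def write_graph(g: Graph, path, weighted: bool | None = None) -> None:
    """Edge-list TSV for one graph; the header carries n_vertices."""
    if weighted is None:
        weighted = not g.is_binary
    iu, ju = np.nonzero(np.triu(g.adjacency, k=1))
    with open(path, "w") as fh:
        fh.write(f"# n_vertices={g.n_vertices}\n")
        fh.write("u\tv\tweight\n" if weighted else "u\tv\n")
        for a, b in zip(iu, ju):
            if weighted:
                fh.write(f"{a}\t{b}\t{float(g.adjacency[a, b])!r}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_graph(path, n_vertices: int | None = None, one_based: bool = False) -> Graph:
    """Read an edge-list TSV written by :func:`write_graph`.

    ``one_based=True`` converts 1-based vertex ids on input.
    """
    path = Path(path)
    n = n_vertices
    edges: list[tuple[int, int, float]] = []
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "n_vertices=" in line:
                    n = int(line.split("n_vertices=")[1])
                continue
            parts = line.split("\t")
            if parts[0] == "u":  # header row
                continue
            try:
                u, v = int(parts[0]), int(parts[1])
                w = float(parts[2]) if len(parts) > 2 else 1.0
            except (ValueError, IndexError):
                raise FormatError(f"{path}:{lineno}: malformed edge line {line!r}")
            if one_based:
                u, v = u - 1, v - 1
            if u == v:
                raise FormatError(f"{path}:{lineno}: self-loop on vertex {u}")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise FormatError(f"{path}:{lineno}: duplicate edge {key}")
            seen.add(key)
            edges.append((u, v, w))
    if n is None:
        raise FormatError(f"{path}: n_vertices not given in header and not supplied")
    a = np.zeros((n, n))
    for u, v, w in edges:
        if not (0 <= u < n and 0 <= v < n):
            raise FormatError(f"{path}: edge ({u}, {v}) references vertex >= n_vertices={n}")
        a[u, v] = a[v, u] = w
    return Graph(a)


def read_adjacency(path) -> Graph:
    """Dense whitespace-delimited adjacency matrix text."""
    try:
        a = np.loadtxt(path)
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse adjacency matrix: {exc}")
    return Graph(np.atleast_2d(a))


def read_graphml(path) -> Graph:
    """GraphML import (read-only); edge 'weight' attributes are honored."""
    g = nx.read_graphml(path)
    g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    return Graph(nx.to_numpy_array(g, weight="weight"))


def write_graph_series(gs: GraphSeries, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_vertices": gs.n_vertices,
        "T": gs.T,
        "weighted": gs.weighted,
        "label": gs.label,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    for t, g in enumerate(gs.graphs, start=1):
        write_graph(g, directory / f"{t:04d}.tsv", weighted=gs.weighted)


def read_graph_series(directory, one_based: bool = False) -> GraphSeries:
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"{directory}: missing meta.json")
    meta = json.loads(meta_path.read_text())
    n = int(meta["n_vertices"])
    files = sorted(p for p in directory.iterdir() if p.suffix == ".tsv")
    if not files:
        raise FormatError(f"{directory}: no edge-list files found")
    graphs = tuple(read_graph(p, n_vertices=n, one_based=one_based) for p in files)
    return GraphSeries(graphs, label=meta.get("label", directory.name),
                       weighted=bool(meta.get("weighted", False)))


def write_graph_series_set(series: Sequence[GraphSeries], directory) -> None:
    """One subdirectory per series, named by series label."""
    directory = Path(directory)
    for i, gs in enumerate(series):
        write_graph_series(gs, directory / (gs.label or f"series{i+1}"))


def read_graph_series_set(directory, one_based: bool = False) -> list[GraphSeries]:
    directory = Path(directory)
    subdirs = sorted(p for p in directory.iterdir() if (p / "meta.json").exists())
    if not subdirs:
        raise FormatError(f"{directory}: no graph-series subdirectories found")
    return [read_graph_series(p, one_based=one_based) for p in subdirs]


# ---------------------------------------------------------------------------
# feature series


def write_feature_series(fs: FeatureSeries, path) -> None:
    pd.DataFrame(fs.values, columns=list(fs.labels)).to_csv(path, sep="\t", index=False)


def read_feature_series(path, feature_name: str = "spectral_radius") -> FeatureSeries:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse feature series TSV: {exc}")
    if df.isna().any().any():
        raise FormatError(f"{path}: feature series contains missing values")
    try:
        values = df.to_numpy(float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric feature value: {exc}")
    return FeatureSeries(values, tuple(df.columns), feature_name=feature_name)


# ---------------------------------------------------------------------------
# models and results


def model_to_dict(model: VARModel) -> dict:
    """JSON-ready summary: order, labels, intercepts, nested coefficients, sigma."""
    k, p = model.k, model.order
    coeffs = {
        model.labels[i]: {
            model.labels[j]: {str(l): model.coefficient(i, j, l) for l in range(1, p + 1)}
            for j in range(k)
        }
        for i in range(k)
    }
    return {
        "order": p,
        "labels": list(model.labels),
        "intercepts": model.intercepts.tolist(),
        "coefficients": coeffs,
        "sigma": model.sigma.tolist(),
        "sigma_df": model.sigma_df,
        "nobs": model.nobs,
    }


def write_model(model: VARModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def read_model(path) -> dict:
    return json.loads(Path(path).read_text())


def results_to_frame(results: Mapping[tuple[int, int], GCTestResult]) -> pd.DataFrame:
    rows = [
        {
            "source": r.source_label or str(r.source + 1),
            "target": r.target_label or str(r.target + 1),
            "statistic": r.statistic,
            "df": r.df,
            "p_value": r.p_value,
            "method": r.method,
            "n_boot": r.n_boot if r.n_boot is not None else "",
        }
        for _, r in sorted(results.items())
    ]
    return pd.DataFrame(rows)


def write_results(results: Mapping[tuple[int, int], GCTestResult], path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        results_to_frame(results).to_csv(path, sep="\t", index=False)
        return
    payload = []
    for _, r in sorted(results.items()):
        item = {
            "source": r.source_label or str(r.source + 1),
            "target": r.target_label or str(r.target + 1),
            "statistic": r.statistic,
            "df": r.df,
            "p_value": r.p_value,
            "method": r.method,
        }
        if r.n_boot is not None:
            item["n_boot"] = r.n_boot
            item["n_discarded"] = r.n_discarded
        if r.boot_stats is not None:
            item["boot_stats"] = np.asarray(r.boot_stats).tolist()
        payload.append(item)
    path.write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# signals, membership, config


def read_signals(path) -> tuple[np.ndarray, list[str]]:
    """T x n signal TSV with a header of channel labels."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse signal TSV: {exc}")
    if df.isna().any().any():
        raise FormatError(f"{path}: signal matrix contains missing values")
    return df.to_numpy(float), list(df.columns)


def read_membership(path, labels: Sequence[str]) -> list[str]:
    """Two-column TSV (channel, group) covering every channel label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["channel", "group"], dtype=str)
    mapping = dict(zip(df["channel"], df["group"]))
    missing = [lab for lab in labels if lab not in mapping]
    if missing:
        raise FormatError(f"{path}: membership missing channels {missing[:5]}")
    return [mapping[lab] for lab in labels]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def dump_run_config(params: dict, path) -> None:
    """Serialize the effective configuration next to a command's outputs."""
    from . import __version__

    payload = {"version": __version__, **params}
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
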