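"""Time-varying correlation graphs from multivariate signals."""

import numpy as np
import pytest

from graphgranger import (
    ValidationError,
    graph_granger,
    split_subnetworks,
    time_varying_correlation,
)


def test_identical_channels_fully_correlated(rng):
    # weights are 1 wherever the smoothed variance is positive; the few
    # boundary points where the smoothed square undershoots zero are floored
    # to weight 0 (with a warning) per the documented convention
    x = rng.standard_normal(200)
    with pytest.warns(UserWarning, match="variance"):
        gs = time_varying_correlation(np.column_stack([x, x]))
    weights = np.array([g.adjacency[0, 1] for g in gs.graphs])
    good = weights != 0.0
    assert good.mean() > 0.9
    assert np.allclose(weights[good], 1.0, atol=1e-6)


def test_independent_channels_near_zero(rng):
    x = rng.standard_normal((400, 2))
    gs = time_varying_correlation(x, df=8)
    weights = np.array([g.adjacency[0, 1] for g in gs.graphs])
    assert abs(weights.mean()) < 0.15


def test_tracks_sign_change():
    rng = np.random.default_rng(77)
    T = 400
    z = rng.standard_normal(T)
    e = rng.standard_normal(T)
    rho = 0.8
    mix = rho * z + np.sqrt(1 - rho**2) * e
    b = np.where(np.arange(T) < T // 2, mix, -mix)
    gs = time_varying_correlation(np.column_stack([z, b]), df=6)
    w = np.array([g.adjacency[0, 1] for g in gs.graphs])
    # away from the break point the estimate should follow the true sign
    assert w[50:150].mean() > 0.4
    assert w[250:350].mean() < -0.4


def test_df1_collapses_to_static_pearson(rng):
    x = rng.standard_normal((120, 3)) + rng.standard_normal((120, 1))
    gs = time_varying_correlation(x, df=1)
    static = np.corrcoef(x.T)
    for g in gs.graphs:
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(g.adjacency[off], static[off], atol=1e-10)


def test_weights_bounded_and_symmetric(rng):
    x = rng.standard_normal((150, 4))
    gs = time_varying_correlation(x)
    assert gs.weighted
    for g in gs.graphs:
        a = g.adjacency
        assert np.all(np.abs(a) <= 1.0)
        assert np.array_equal(a, a.T)
        assert np.all(np.diag(a) == 0)


def test_split_single_group_identity(rng):
    x = rng.standard_normal((60, 4))
    gs = time_varying_correlation(x)
    parts = split_subnetworks(gs, ["all"] * 4)
    assert set(parts) == {"all"}
    assert np.array_equal(parts["all"].graphs[0].adjacency, gs.graphs[0].adjacency)


def test_split_preserves_group_structure(rng):
    x = rng.standard_normal((60, 6))
    gs = time_varying_correlation(x)
    parts = split_subnetworks(gs, ["L", "L", "L", "R", "R", "R"])
    assert parts["L"].n_vertices == 3 and parts["R"].n_vertices == 3
    # induced subgraph: left block of the full adjacency
    assert np.array_equal(parts["L"].graphs[5].adjacency, gs.graphs[5].adjacency[:3, :3])
    assert np.array_equal(parts["R"].graphs[5].adjacency, gs.graphs[5].adjacency[3:, 3:])


def test_split_membership_errors(rng):
    x = rng.standard_normal((60, 4))
    gs = time_varying_correlation(x)
    with pytest.raises(ValidationError):
        split_subnetworks(gs, ["a", "b", "a"])  # wrong length
    with pytest.raises(ValidationError):
        split_subnetworks(gs, {0: "a", 1: "a", 2: "b"})  # vertex 3 missing


def test_feeds_pipeline():
    # two coupled subnetworks -> weighted graph series -> causality pipeline
    rng = np.random.default_rng(5)
    T = 120
    driver = np.zeros(T)
    for t in range(1, T):
        driver[t] = 0.7 * driver[t - 1] + rng.standard_normal()
    left = driver[:, None] * np.array([1.0, 0.8, 0.6]) + 0.6 * rng.standard_normal((T, 3))
    right = rng.standard_normal((T, 3))
    gs = time_varying_correlation(np.column_stack([left, right]), df=8)
    parts = split_subnetworks(gs, ["L"] * 3 + ["R"] * 3)
    results, model = graph_granger(list(parts.values()), order=1, allow_empty=True)
    assert len(results) == 2
    assert all(0 <= r.p_value <= 1 for r in results.values())


def test_bad_input_shapes():
    with pytest.raises(ValidationError):
        time_varying_correlation(np.zeros((5, 2)))  # too short
    with pytest.raises(ValidationError):
        time_varying_correlation(np.full((50, 2), np.nan))
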