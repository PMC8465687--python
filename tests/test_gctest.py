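"""Wald and bootstrap Granger non-causality tests."""

import dataclasses

import numpy as np
import pytest
import scipy.stats
from statsmodels.tsa.api import VAR as SMVAR

from graphgranger import (
    ParameterError,
    bootstrap_test,
    contrast_matrix,
    fit,
    simulate_latent,
    wald_statistic,
    wald_test,
)
from graphgranger import test_all_pairs as all_pairs_gc


def test_contrast_matrix_structure():
    C = contrast_matrix(k=3, p=2, source=1)
    assert C.shape == (2, 6)
    assert np.all(C.sum(axis=1) == 1)
    assert np.linalg.matrix_rank(C) == 2
    # selects a_{source,.}^l rows under series-major/lag-minor ordering
    assert C[0, 2] == 1 and C[1, 3] == 1


def test_w_zero_when_cross_coefficients_zero():
    lat = simulate_latent(1, 200, seed=4)
    m = fit(lat, 1)
    zeroed = m.coefficients.copy()
    zeroed[m.lag_row_indices(0), 1] = 0.0
    m0 = dataclasses.replace(m, coefficients=zeroed)
    assert wald_statistic(m0, 0, 1) == 0.0
    res = wald_test(m0, 0, 1)
    assert res.p_value == pytest.approx(1.0)


def test_scalar_hand_oracle_p1():
    # p = 1 reduces the quadratic form to b^2 / ([ (G'G)^-1 ]_ii * sigma_jj),
    # computed here with explicit cofactor determinants
    y = np.array([[1.0, 2.0], [2.0, 1.5], [1.2, 2.2], [3.0, 0.5], [2.1, 1.0], [0.7, 2.6]])
    m = fit(y, 1)
    G = m.design
    GtG = G.T @ G
    i = 0  # design column of series 0, lag 1
    minor = np.delete(np.delete(GtG, i, axis=0), i, axis=1)
    inv_ii = np.linalg.det(minor) / np.linalg.det(GtG)  # cofactor formula
    b = m.coefficient(0, 1, 1)
    w_oracle = b * b / (inv_ii * m.sigma[1, 1])
    assert wald_statistic(m, 0, 1) == pytest.approx(w_oracle, rel=1e-10)
    res = wald_test(m, 0, 1)
    assert res.p_value == pytest.approx(scipy.stats.chi2.sf(res.statistic, 1))


def test_matches_statsmodels_causality_wald():
    lat = simulate_latent(4, 500, seed=10)
    p = 2
    m = fit(lat, p)
    sm = SMVAR(lat.values).fit(p, trend="c")
    for source, target in [(0, 1), (2, 3), (1, 0)]:
        tc = sm.test_causality(target, source, kind="wald")
        assert wald_statistic(m, source, target) == pytest.approx(
            float(tc.test_statistic), rel=1e-8
        )


def test_self_causality_rejected():
    lat = simulate_latent(1, 100, seed=1)
    m = fit(lat, 1)
    with pytest.raises(ParameterError):
        wald_statistic(m, 1, 1)


def test_w_invariant_to_noninvolved_relabeling():
    lat = simulate_latent(4, 300, seed=6)
    m = fit(lat, 1)
    w = wald_statistic(m, 0, 1)
    swapped = lat.values[:, [0, 1, 3, 2]]  # permute the two uninvolved series
    m2 = fit(swapped, 1)
    assert wald_statistic(m2, 0, 1) == pytest.approx(w, rel=1e-9)


def test_null_statistics_follow_chi2():
    ws = []
    for rep in range(300):
        lat = simulate_latent(1, 200, seed=np.random.SeedSequence([515, rep]))
        ws.append(wald_statistic(fit(lat, 1), 0, 1))
    stat, pval = scipy.stats.kstest(ws, scipy.stats.chi2(1).cdf)
    assert pval > 0.01


def test_bootstrap_single_replicate_pvalue():
    lat = simulate_latent(1, 60, seed=3)
    res = bootstrap_test(lat, 1, 0, 1, n_boot=1, seed=9)
    assert res.p_value in (0.0, 1.0)
    res_s = bootstrap_test(lat, 1, 0, 1, n_boot=1, seed=9, smoothed=True)
    assert res_s.p_value in (0.5, 1.0)


def test_bootstrap_deterministic():
    lat = simulate_latent(2, 80, seed=12)
    a = bootstrap_test(lat, 1, 0, 1, n_boot=50, seed=99, keep_boot_stats=True)
    b = bootstrap_test(lat, 1, 0, 1, n_boot=50, seed=99, keep_boot_stats=True)
    assert a.p_value == b.p_value
    assert np.array_equal(a.boot_stats, b.boot_stats)
    c = bootstrap_test(lat, 1, 0, 1, n_boot=50, seed=100)
    assert a.statistic == pytest.approx(c.statistic)  # observed W is seed-free


def test_bootstrap_detects_strong_causality():
    lat = simulate_latent(2, 150, seed=8)
    res = bootstrap_test(lat, 1, 0, 1, n_boot=200, seed=5)
    assert res.p_value < 0.05


def test_bootstrap_agrees_with_wald_on_long_series():
    agree = 0
    reps = 20
    for rep in range(reps):
        lat = simulate_latent(1, 500, seed=np.random.SeedSequence([77, rep]))
        m = fit(lat, 1)
        pw = wald_test(m, 0, 1).p_value
        pb = bootstrap_test(lat, 1, 0, 1, n_boot=200, seed=rep).p_value
        if abs(pw - pb) <= 0.05:
            agree += 1
    assert agree >= int(0.9 * reps)


def test_all_pairs_counts_and_selfconsistency():
    lat2 = simulate_latent(1, 100, seed=2)
    res2 = all_pairs_gc(lat2, 1, method="wald")
    assert set(res2) == {(0, 1), (1, 0)}

    lat4 = simulate_latent(5, 100, seed=2)
    res4 = all_pairs_gc(lat4, 1, method="wald")
    assert len(res4) == 12

    boot = all_pairs_gc(lat2, 1, method="bootstrap", n_boot=30, seed=41)
    for (i, j), r in boot.items():
        single = bootstrap_test(
            lat2, 1, i, j, n_boot=30, seed=np.random.SeedSequence([41, i, j])
        )
        assert r.p_value == single.p_value
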