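"""OLS VAR estimation: design construction, coefficients, covariance, AIC."""

import numpy as np
import pytest
from statsmodels.tsa.api import VAR as SMVAR

from graphgranger import (
    FeatureSeries,
    InsufficientDataError,
    SingularDesignError,
    build_design,
    fit,
    select_order,
    simulate_latent,
)


def test_design_univariate_lag1():
    y = np.array([[1.0], [2.0], [3.0], [4.0]])
    Y, Z = build_design(y, 1)
    assert np.array_equal(Y, [[2.0], [3.0], [4.0]])
    assert np.array_equal(Z[:, 0], [1.0, 2.0, 3.0])
    assert np.array_equal(Z[:, 1], [1.0, 1.0, 1.0])  # intercept column last


def test_design_bivariate_lag2_hand_built():
    vals = np.arange(10, dtype=float).reshape(5, 2)  # y[t] = (2t, 2t+1)
    Y, Z = build_design(vals, 2)
    assert Y.shape == (3, 2) and Z.shape == (3, 5)
    # row for t=2 (0-based): series-major, lag-minor: y[1,0], y[0,0], y[1,1], y[0,1], 1
    assert np.array_equal(Z[0], [vals[1, 0], vals[0, 0], vals[1, 1], vals[0, 1], 1.0])
    assert np.array_equal(Z[2], [vals[3, 0], vals[2, 0], vals[3, 1], vals[2, 1], 1.0])
    assert np.array_equal(Y[0], vals[2])


def test_design_too_short():
    vals = np.random.default_rng(0).standard_normal((5, 2))
    with pytest.raises(InsufficientDataError):
        build_design(vals, 4)


def test_noiseless_ar1_exact():
    y = 0.9 ** np.arange(30).reshape(-1, 1)
    m = fit(y, 1)
    assert m.coefficient(0, 0, 1) == pytest.approx(0.9, abs=1e-12)
    assert m.intercepts[0] == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(m.sigma, 0.0, atol=1e-20)


def test_matches_pseudo_inverse_oracle():
    rng = np.random.default_rng(11)
    for _ in range(50):
        T = int(rng.integers(20, 60))
        k = int(rng.integers(1, 4))
        p = int(rng.integers(1, 3))
        vals = rng.standard_normal((T, k))
        m = fit(vals, p)
        _, Z = build_design(vals, p)
        B_oracle = np.linalg.pinv(Z) @ vals[p:]
        assert np.allclose(m.coefficients, B_oracle[:-1], atol=1e-8)
        assert np.allclose(m.intercepts, B_oracle[-1], atol=1e-8)


def test_matches_statsmodels():
    lat = simulate_latent(4, 400, seed=21)
    p = 2
    m = fit(lat, p)
    sm = SMVAR(lat.values).fit(p, trend="c")
    # statsmodels stacks intercept first, then lag-major blocks
    k = lat.k
    for i in range(k):
        for j in range(k):
            for l in range(1, p + 1):
                sm_coef = sm.params[1 + (l - 1) * k + i, j]
                assert m.coefficient(i, j, l) == pytest.approx(sm_coef, abs=1e-10)
    assert np.allclose(m.intercepts, sm.params[0], atol=1e-10)
    assert np.allclose(m.sigma, sm.sigma_u, atol=1e-10)


def test_residuals_orthogonal_to_design():
    lat = simulate_latent(3, 200, seed=5)
    m = fit(lat, 1)
    assert np.max(np.abs(m.design.T @ m.residuals)) < 1e-8


def test_refit_on_fitted_values_reproduces_beta():
    lat = simulate_latent(1, 150, seed=9)
    m = fit(lat, 1)
    # reconstruct the series from fitted values + residuals: identical to input
    fitted_plus_resid = m.design @ np.vstack([m.coefficients, m.intercepts]) + m.residuals
    rebuilt = np.vstack([lat.values[: m.order], fitted_plus_resid])
    m2 = fit(rebuilt, m.order)
    assert np.allclose(m.coefficients, m2.coefficients, atol=1e-12)


def test_sigma_positive_semidefinite():
    lat = simulate_latent(5, 300, seed=13)
    m = fit(lat, 2)
    eigs = np.linalg.eigvalsh(m.sigma)
    assert np.all(eigs > -1e-12)
    assert np.allclose(m.sigma, m.sigma.T)


def test_sigma_df_modes_differ_by_known_factor():
    lat = simulate_latent(1, 100, seed=3)
    a = fit(lat, 1, sigma_df="intercept")
    b = fit(lat, 1, sigma_df="lags-only")
    T_eff, k, p = 99, 2, 1
    assert np.allclose(a.sigma * (T_eff - (k * p + 1)), b.sigma * (T_eff - k * p))


def test_constant_series_singular():
    vals = np.column_stack([np.ones(30), np.random.default_rng(0).standard_normal(30)])
    with pytest.raises(SingularDesignError) as exc:
        fit(vals, 1)
    assert exc.value.columns  # diagnostic names offending columns


def test_scenario2_cross_coefficient_recovered():
    lat = simulate_latent(2, 10_000, seed=77)
    m = fit(lat, 1)
    assert m.coefficient(0, 1, 1) == pytest.approx(0.5, abs=0.03)
    assert m.coefficient(1, 1, 1) == pytest.approx(0.0, abs=0.03)


def test_select_order_recovers_var2():
    # scenario 4 has a genuine lag-2 dependence
    lat = simulate_latent(4, 2000, seed=31)
    assert select_order(lat, 4) == 2


def test_select_order_white_noise_prefers_smallest():
    rng = np.random.default_rng(8)
    vals = rng.standard_normal((500, 2))
    assert select_order(vals, 5) == 1


def test_select_order_pmax_one():
    lat = simulate_latent(1, 50, seed=2)
    assert select_order(lat, 1) == 1
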