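"""Granger non-causality tests on a fitted VAR.

Series i does not Granger-cause series j exactly when all cross coefficients
a_{i,j}^l (l = 1..p) vanish.  The null H0: C beta_j = 0 — with C the p x (kp)
contrast matrix selecting those coefficients — is tested two ways:

* Wald's test: W = (C b_j)' [C (Z'Z)^-1 C']^-1 (C b_j) / Sigma_jj, compared
  to a chi-squared distribution with rank(C) = p degrees of freedom.  Valid
  asymptotically (long series).

* A parametric bootstrap for short series: the fitted model with the tested
  coefficients zeroed (all others kept) is recursed forward, driven by whole
  residual rows resampled with replacement — joint resampling preserves the
  contemporaneous error correlation.  Each bootstrap path is refitted and its
  Wald statistic W* recomputed; the p-value is the fraction of W* at least as
  large as the observed W.

Bootstrap replicates are simulated and refitted in a single vectorized batch,
with per-replicate random substreams so results are reproducible and
independent of batch size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.stats

from . import var as _var
from .exceptions import ParameterError, SingularDesignError
from .features import FeatureSeries

_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class GCTestResult:
    """One directed Granger non-causality test."""

    source: int
    target: int
    statistic: float
    df: int
    p_value: float
    method: str                      # "wald_chi2" or "bootstrap"
    source_label: str = ""
    target_label: str = ""
    n_boot: int | None = None
    n_discarded: int = 0
    boot_stats: np.ndarray | None = None


def contrast_matrix(k: int, p: int, source: int) -> np.ndarray:
    """Binary p x (kp) matrix selecting a_{source,j}^l for l = 1..p.

    Row l has a single one in column source*p + l, matching the
    series-major/lag-minor coefficient ordering of :mod:`graphgranger.var`.
    """
    if not 0 <= source < k:
        raise ParameterError(f"source index {source} out of range for k={k}")
    C = np.zeros((p, k * p))
    for l in range(p):
        C[l, source * p + l] = 1.0
    return C


def _check_pair(model: _var.VARModel, source: int, target: int) -> None:
    k = model.k
    for name, idx in (("source", source), ("target", target)):
        if not 0 <= idx < k:
            raise ParameterError(f"{name} index {idx} out of range for k={k}")
    if source == target:
        raise ParameterError(
            "source and target must differ: the model only defines cross-series hypotheses"
        )


def wald_statistic(model: _var.VARModel, source: int, target: int) -> float:
    """Wald statistic W for H0: series ``source`` does not cause ``target``."""
    _check_pair(model, source, target)
    p = model.order
    sel = model.lag_row_indices(source)
    cb = model.coefficients[sel, target]
    G = model.design
    GtG = G.T @ G
    try:
        inv = np.linalg.inv(GtG)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(f"Z'Z is singular: {exc}")
    M = inv[np.ix_(sel, sel)]
    sv = np.linalg.svd(M, compute_uv=False)
    if sv[-1] <= _RANK_RTOL * sv[0]:
        raise SingularDesignError("C (Z'Z)^-1 C' is numerically singular")
    w = float(cb @ np.linalg.solve(M, cb) / model.sigma[target, target])
    return max(w, 0.0)


def wald_test(model: _var.VARModel, source: int, target: int) -> GCTestResult:
    """Asymptotic chi-squared Wald test of Granger non-causality."""
    w = wald_statistic(model, source, target)
    p = model.order
    return GCTestResult(
        source=source,
        target=target,
        statistic=w,
        df=p,
        p_value=float(scipy.stats.chi2.sf(w, p)),
        method="wald_chi2",
        source_label=model.labels[source],
        target_label=model.labels[target],
    )


def _batched_wald(paths: np.ndarray, p: int, source: int, target: int, sigma_df: str):
    """Refit a VAR(p) to each path in a batch and return per-path W.

    ``paths`` is (n_boot, T, k).  Returns (W, ok) where ``ok`` flags the
    replicates whose refit design was numerically full rank.
    """
    nb, T, k = paths.shape
    N = T - p
    cols = [paths[:, p - l : T - l, i] for i in range(k) for l in range(1, p + 1)]
    G = np.stack(cols + [np.ones((nb, N))], axis=2)            # (nb, N, d)
    Yb = paths[:, p:, :]                                       # (nb, N, k)
    GtG = np.einsum("bni,bnj->bij", G, G)
    sv = np.linalg.svd(GtG, compute_uv=False)
    ok = sv[:, -1] > _RANK_RTOL * sv[:, 0]
    GtG_safe = np.where(ok[:, None, None], GtG, np.eye(GtG.shape[1]))
    inv = np.linalg.inv(GtG_safe)
    beta = inv @ np.einsum("bni,bnj->bij", G, Yb)              # (nb, d, k)
    resid = Yb - np.einsum("bni,bij->bnj", G, beta)
    dof = N - (k * p + (1 if sigma_df == "intercept" else 0))
    sigma_jj = np.einsum("bn,bn->b", resid[:, :, target], resid[:, :, target]) / dof
    sel = [source * p + l for l in range(p)]
    cb = beta[:, sel, target]                                  # (nb, p)
    M = inv[:, sel][:, :, sel]                                 # (nb, p, p)
    svm = np.linalg.svd(M, compute_uv=False)
    ok &= svm[:, -1] > _RANK_RTOL * svm[:, 0]
    ok &= sigma_jj > 0
    M_safe = np.where(ok[:, None, None], M, np.eye(p))
    w = np.einsum("bi,bij,bj->b", cb, np.linalg.inv(M_safe), cb)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(ok, np.maximum(w / sigma_jj, 0.0), np.nan)
    return w, ok


def bootstrap_test(
    y: FeatureSeries | np.ndarray,
    p: int,
    source: int,
    target: int,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    sigma_df: str = "intercept",
    keep_boot_stats: bool = False,
    smoothed: bool = False,
) -> GCTestResult:
    """Parametric-bootstrap Granger non-causality test.

    Fits the unrestricted VAR(p), computes the observed W, then simulates
    ``n_boot`` series from the null model (tested coefficients zeroed,
    everything else — including the intercept — kept as estimated), each
    driven by residual rows resampled jointly with replacement and started
    from the first p observed values.  The p-value is the fraction of
    refitted W* >= W; ``smoothed=True`` uses (1 + #{W* >= W}) / (1 + n_boot)
    instead, which never returns exactly zero.
    """
    if n_boot < 1:
        raise ParameterError(f"n_boot must be >= 1, got {n_boot}")
    model = _var.fit(y, p, sigma_df=sigma_df)
    _check_pair(model, source, target)
    w_obs = wald_statistic(model, source, target)
    k = model.k
    T = model.nobs
    N = T - p

    beta_null = model.coefficients.copy()
    beta_null[model.lag_row_indices(source), target] = 0.0

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_boot)
    idx = np.stack(
        [np.random.default_rng(c).integers(0, N, size=N) for c in children]
    )                                                          # (n_boot, N)
    innov = model.residuals[idx]                               # (n_boot, N, k)

    y_vals = y.values if isinstance(y, FeatureSeries) else np.atleast_2d(np.asarray(y, float))
    if y_vals.shape[0] == 1:
        y_vals = y_vals.T
    paths = np.empty((n_boot, T, k))
    paths[:, :p, :] = y_vals[:p]
    v = model.intercepts
    for t in range(p, T):
        # lag block, series-major lag-minor, batched over replicates
        z = paths[:, t - p : t, :][:, ::-1, :].transpose(0, 2, 1).reshape(n_boot, k * p)
        paths[:, t, :] = v + z @ beta_null + innov[:, t - p, :]

    w_star, ok = _batched_wald(paths, p, source, target, sigma_df)
    n_eff = int(ok.sum())
    if n_eff == 0:
        raise SingularDesignError("every bootstrap replicate produced a singular refit")
    if n_eff < n_boot:
        import warnings

        warnings.warn(
            f"discarded {n_boot - n_eff} bootstrap replicate(s) with singular refits",
            stacklevel=2,
        )
    w_keep = w_star[ok]
    n_ge = int(np.sum(w_keep >= w_obs))
    p_value = (1 + n_ge) / (1 + n_eff) if smoothed else n_ge / n_eff
    return GCTestResult(
        source=source,
        target=target,
        statistic=w_obs,
        df=p,
        p_value=float(p_value),
        method="bootstrap",
        source_label=model.labels[source],
        target_label=model.labels[target],
        n_boot=n_eff,
        n_discarded=n_boot - n_eff,
        boot_stats=w_keep if keep_boot_stats else None,
    )


def test_all_pairs(
    y: FeatureSeries | np.ndarray,
    p: int,
    method: str = "wald",
    n_boot: int = 1000,
    seed: int = 0,
    sigma_df: str = "intercept",
    keep_boot_stats: bool = False,
    smoothed: bool = False,
) -> Mapping[tuple[int, int], GCTestResult]:
    """All k(k-1) directed tests; bootstrap seeds derived per ordered pair."""
    if method not in ("wald", "bootstrap"):
        raise ParameterError(f"method must be 'wald' or 'bootstrap', got {method!r}")
    model = _var.fit(y, p, sigma_df=sigma_df)
    k = model.k
    if k < 2:
        raise ParameterError("need at least two series to test causality")
    results: dict[tuple[int, int], GCTestResult] = {}
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if method == "wald":
                results[(i, j)] = wald_test(model, i, j)
            else:
                pair_seed = np.random.SeedSequence([int(seed), i, j])
                results[(i, j)] = bootstrap_test(
                    y, p, i, j,
                    n_boot=n_boot,
                    seed=pair_seed,
                    sigma_df=sigma_df,
                    keep_boot_stats=keep_boot_stats,
                    smoothed=smoothed,
                )
    return results
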