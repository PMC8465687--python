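"""Vector autoregression fitted by ordinary least squares.

The k-dimensional VAR(p) model

    y_{j,t} = v_j + sum_{i=1..k} sum_{l=1..p} a_{i,j}^l y_{i,t-l} + e_{j,t}

is written in matrix form Y = Z beta + u and solved by least squares.  The
lag columns of Z are ordered series-major, lag-minor: the column holding
y_{i,t-l} has index (i-1)*p + (l-1).  An intercept column is appended last;
its estimates are reported separately from the lag coefficients.

The residual covariance uses the degrees-of-freedom denominator
(T - p) - (kp + 1), counting the intercept among the estimated parameters
(``sigma_df="intercept"``, the default).  ``sigma_df="lags-only"`` uses
(T - p) - kp, i.e. counts only the lag coefficients.

Order selection is by AIC over a common effective sample: every candidate
order is fitted to the rows available at the largest candidate, so the
log-determinant terms are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError, SingularDesignError
from .features import FeatureSeries

_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class VARModel:
    """A fitted VAR(p): coefficients, intercepts, residuals and covariance.

    ``coefficients`` is the (kp) x k matrix beta; entry [(i)*p + (l-1), j]
    is a_{i,j}^l, the effect of series i at lag l on series j (0-based i, j).
    ``design`` is the (T-p) x (kp+1) regressor matrix including the trailing
    intercept column; ``response`` the (T-p) x k matrix of left-hand sides.
    """

    order: int
    labels: tuple[str, ...]
    intercepts: np.ndarray     # (k,)
    coefficients: np.ndarray   # (kp, k)
    residuals: np.ndarray      # (T-p, k)
    sigma: np.ndarray          # (k, k)
    design: np.ndarray         # (T-p, kp+1)
    response: np.ndarray       # (T-p, k)
    nobs: int                  # original series length T
    sigma_df: str = "intercept"

    @property
    def k(self) -> int:
        return len(self.labels)

    def coefficient(self, source: int, target: int, lag: int) -> float:
        """a_{source,target}^lag with 0-based series indices, lag in 1..p."""
        if not 1 <= lag <= self.order:
            raise IndexError(f"lag must be in 1..{self.order}")
        return float(self.coefficients[source * self.order + (lag - 1), target])

    def lag_row_indices(self, source: int) -> list[int]:
        """Design/coefficient row indices of all lags of one source series."""
        p = self.order
        return [source * p + l for l in range(p)]

    def simulate(self, innovations: np.ndarray, initial: np.ndarray) -> np.ndarray:
        """Recurse the fitted model forward, driven by given innovation rows.

        ``initial`` supplies the first p values (p x k); ``innovations`` one
        row per generated time point.  Returns the full (p + len) x k path.
        """
        p, k = self.order, self.k
        steps = innovations.shape[0]
        out = np.empty((p + steps, k))
        out[:p] = initial
        beta, v = self.coefficients, self.intercepts
        for t in range(p, p + steps):
            # series-major, lag-minor: rows t-1 .. t-p per series, flattened
            z = out[t - p : t][::-1].T.ravel()
            out[t] = v + z @ beta + innovations[t - p]
        return out


def build_design(y: FeatureSeries | np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Response Y and lagged design Z (with trailing intercept column).

    Y stacks y_t for t = p+1 .. T; the Z row for time t holds
    (y_{1,t-1}, ..., y_{1,t-p}, ..., y_{k,t-1}, ..., y_{k,t-p}, 1).
    """
    vals = y.values if isinstance(y, FeatureSeries) else np.atleast_2d(np.asarray(y, float))
    if vals.ndim == 2 and vals.shape[0] == 1:
        vals = vals.T
    T, k = vals.shape
    if p < 1:
        raise InsufficientDataError(f"order must be >= 1, got {p}")
    if T - p < 2:
        raise InsufficientDataError(
            f"series length T={T} leaves fewer than two rows at order p={p}"
        )
    Y = vals[p:]
    # lag l column for series i: vals[p-l : T-l, i]
    cols = [vals[p - l : T - l, i] for i in range(k) for l in range(1, p + 1)]
    Z = np.column_stack(cols + [np.ones(T - p)])
    return Y, Z


def _check_rank(Z: np.ndarray) -> None:
    s = np.linalg.svd(Z, compute_uv=False)
    if s[-1] <= _RANK_RTOL * s[0]:
        # identify the columns most involved in the null space for diagnostics
        _, _, vt = np.linalg.svd(Z)
        null_weights = np.abs(vt[-1])
        bad = [int(i) for i in np.nonzero(null_weights > 0.1)[0]]
        raise SingularDesignError(
            f"design matrix is rank deficient (columns {bad} are collinear; "
            "constant or duplicated series?)",
            columns=bad,
        )


def fit(y: FeatureSeries | np.ndarray, p: int, sigma_df: str = "intercept") -> VARModel:
    """Fit a VAR(p) by OLS.

    beta solves the least-squares problem min ||Y - Z beta||; the residual
    covariance divides u'u by the degrees of freedom selected by
    ``sigma_df`` (see module docstring).
    """
    if sigma_df not in ("intercept", "lags-only"):
        raise ValueError(f"sigma_df must be 'intercept' or 'lags-only', got {sigma_df!r}")
    labels = y.labels if isinstance(y, FeatureSeries) else None
    Y, Z = build_design(y, p)
    n_rows, k = Y.shape
    _check_rank(Z)
    B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    resid = Y - Z @ B
    n_params = k * p + (1 if sigma_df == "intercept" else 0)
    dof = n_rows - n_params
    if dof <= 0:
        raise InsufficientDataError(
            f"no residual degrees of freedom: (T-p)={n_rows}, parameters={n_params}"
        )
    sigma = resid.T @ resid / dof
    if labels is None:
        labels = tuple(f"y{i+1}" for i in range(k))
    return VARModel(
        order=p,
        labels=tuple(labels),
        intercepts=B[-1].copy(),
        coefficients=B[:-1].copy(),
        residuals=resid,
        sigma=sigma,
        design=Z,
        response=Y,
        nobs=n_rows + p,
        sigma_df=sigma_df,
    )


def select_order(y: FeatureSeries | np.ndarray, p_max: int, sigma_df: str = "intercept") -> int:
    """Choose the VAR order in 1..p_max by AIC; ties go to the smaller order.

    AIC(p) = ln det Sigma_mle(p) + 2 p k^2 / T_eff, with Sigma_mle the
    maximum-likelihood (unadjusted) residual covariance and all candidates
    fitted on the rows available at p_max.
    """
    if p_max < 1:
        raise InsufficientDataError(f"p_max must be >= 1, got {p_max}")
    vals = y.values if isinstance(y, FeatureSeries) else np.atleast_2d(np.asarray(y, float))
    if vals.shape[0] == 1:
        vals = vals.T
    T, k = vals.shape
    T_eff = T - p_max
    if T_eff < k * p_max + 2:
        raise InsufficientDataError(
            f"series length T={T} too short to compare orders up to {p_max} with k={k}"
        )
    Y_full = vals[p_max:]
    best_p, best_aic = None, np.inf
    errors = []
    for p in range(1, p_max + 1):
        # align: responses always start at row p_max
        cols = [vals[p_max - l : T - l, i] for i in range(k) for l in range(1, p + 1)]
        Z = np.column_stack(cols + [np.ones(T_eff)])
        try:
            _check_rank(Z)
        except SingularDesignError as exc:
            errors.append(exc)
            continue
        B, *_ = np.linalg.lstsq(Z, Y_full, rcond=None)
        resid = Y_full - Z @ B
        sign, logdet = np.linalg.slogdet(resid.T @ resid / T_eff)
        aic = (logdet if sign > 0 else -np.inf) + 2.0 * p * k * k / T_eff
        if aic < best_aic:  # strict: ties keep the smaller order
            best_p, best_aic = p, aic
    if best_p is None:
        raise SingularDesignError(f"all candidate orders 1..{p_max} gave singular designs") from (
            errors[-1] if errors else None
        )
    return best_p
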