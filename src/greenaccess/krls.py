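"""Kernel regularized least squares (KRLS) with closed-form marginal effects.

Gaussian-kernel ridge regression: with K_ij = exp(-||x_i - x_j||^2 / sigma2)
on standardized covariates, the coefficients are c = (K + lambda I)^{-1} y.
The fitted surface yhat(x) = sum_j c_j k(x, x_j) is differentiable, giving
closed-form pointwise partial derivatives

    d yhat_i / d x_d = -(2 / sigma2) * sum_j c_j K_ij (x_id - x_jd)

which are read as heterogeneous marginal effects and summarized by their
average and P25/P50/P75 quantiles across observations.  The ridge penalty
lambda is chosen by exact leave-one-out cross-validation via the hat-matrix
identity e_i^loo = (y_i - yhat_i) / (1 - H_ii); everything is deterministic.

Inference on the average effect uses the delta method: the average derivative
is linear in c, and cov(c) = sigma_hat^2 (K + lambda I)^{-2}.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

_LOG_LAMBDA_RANGE = (np.log(1e-6), np.log(1e3))
_GOLDEN_TOL = 1e-4


@dataclass
class StandardizedDesign:
    """Covariates and response standardized to mean 0, sd 1 (sample sd)."""

    X: np.ndarray
    y: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    names: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def D(self) -> int:
        return self.X.shape[1]

    def unstandardize_X(self) -> np.ndarray:
        return self.X * self.x_sd + self.x_mean

    def unstandardize_y(self) -> np.ndarray:
        return self.y * self.y_sd + self.y_mean


def standardize(
    X_raw: np.ndarray, y_raw: np.ndarray, names: list[str] | None = None
) -> StandardizedDesign:
    """Center and scale columns of X and y (sample sd, ddof=1).

    Constant columns cannot be scaled and raise a ValueError naming the
    offending column.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    if X_raw.ndim == 1:
        X_raw = X_raw[:, None]
    y_raw = np.asarray(y_raw, dtype=float).ravel()
    n, D = X_raw.shape
    if n <= D:
        raise ValueError(f"need n > D, got n={n}, D={D}")
    if names is None:
        names = [f"x{d + 1}" for d in range(D)]
    x_mean = X_raw.mean(axis=0)
    x_sd = X_raw.std(axis=0, ddof=1)
    for d in range(D):
        if np.ptp(X_raw[:, d]) == 0 or x_sd[d] == 0 or not np.isfinite(x_sd[d]):
            raise ValueError(f"covariate {names[d]!r} is constant; cannot standardize")
    y_sd = float(y_raw.std(ddof=1))
    if y_sd == 0:
        # constant response: keep scale 1 so the (degenerate) fit is zeros
        y_sd = 1.0
    y_mean = float(y_raw.mean())
    return StandardizedDesign(
        X=(X_raw - x_mean) / x_sd,
        y=(y_raw - y_mean) / y_sd,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        names=list(names),
    )


def gaussian_kernel(X: np.ndarray, sigma2: float) -> np.ndarray:
    """K_ij = exp(-||x_i - x_j||^2 / sigma2); symmetric, unit diagonal."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-d2 / sigma2)
    # exact symmetry and unit diagonal guard against round-off
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return K


def gaussian_cross_kernel(X_new: np.ndarray, X: np.ndarray, sigma2: float) -> np.ndarray:
    """k(x_new, x_train) matrix for prediction."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d2 = (
        np.sum(X_new**2, axis=1)[:, None]
        + np.sum(X**2, axis=1)[None, :]
        - 2.0 * (X_new @ X.T)
    )
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / sigma2)


@dataclass
class KRLSFit:
    """Fitted KRLS model (in standardized space)."""

    sigma2: float
    lam: float
    c: np.ndarray
    fitted: np.ndarray
    loo_errors: np.ndarray
    loo_sse: float
    sigma_hat2: float
    K: np.ndarray
    evals: np.ndarray
    evecs: np.ndarray

    def predict_standardized(self, X_new: np.ndarray, X_train: np.ndarray) -> np.ndarray:
        return gaussian_cross_kernel(X_new, X_train, self.sigma2) @ self.c


def _loo_quantities(evals: np.ndarray, Q: np.ndarray, Qty: np.ndarray, y: np.ndarray, lam: float):
    """Fitted values, hat diagonal and LOO errors for a given lambda."""
    s = evals / (evals + lam)
    fitted = Q @ (s * Qty)
    hdiag = (Q**2) @ s
    denom = 1.0 - hdiag
    # hdiag -> 1 only as lam -> 0 on full-rank K; clip for safety
    denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
    e_loo = (y - fitted) / denom
    return fitted, hdiag, e_loo


def fit(
    design: StandardizedDesign,
    sigma2: float | None = None,
    lam: float | str = "loo",
) -> KRLSFit:
    """Fit KRLS; lambda chosen by golden-section search on log lambda
    minimizing the exact leave-one-out SSE (default), or fixed if numeric.

    The default bandwidth is sigma2 = D, the number of covariates.
    """
    if sigma2 is None:
        sigma2 = float(design.D)
    K = gaussian_kernel(design.X, sigma2)
    y = design.y
    evals, Q = np.linalg.eigh(K)
    evals = np.maximum(evals, 0.0)
    Qty = Q.T @ y

    def loo_sse(log_lam: float) -> float:
        _, _, e = _loo_quantities(evals, Q, Qty, y, np.exp(log_lam))
        return float(e @ e)

    if lam == "loo":
        lo, hi = _LOG_LAMBDA_RANGE
        phi = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c1 = b - phi * (b - a)
        c2 = a + phi * (b - a)
        f1, f2 = loo_sse(c1), loo_sse(c2)
        while b - a > _GOLDEN_TOL:
            if f1 <= f2:
                b, c2, f2 = c2, c1, f1
                c1 = b - phi * (b - a)
                f1 = loo_sse(c1)
            else:
                a, c1, f1 = c1, c2, f2
                c2 = a + phi * (b - a)
                f2 = loo_sse(c2)
        lam_val = float(np.exp(0.5 * (a + b)))
    else:
        lam_val = float(lam)
        if lam_val <= 0:
            raise ValueError("lambda must be > 0")

    if np.min(evals + lam_val) < 1e-14:
        raise np.linalg.LinAlgError(
            f"(K + lambda I) numerically singular at lambda={lam_val:g}; "
            "raise the lambda floor"
        )
    fitted, hdiag, e_loo = _loo_quantities(evals, Q, Qty, y, lam_val)
    c = Q @ (Qty / (evals + lam_val))
    resid = y - fitted
    edf = float(design.n - hdiag.sum())
    edf = max(edf, 1.0)
    sigma_hat2 = float(resid @ resid) / edf
    return KRLSFit(
        sigma2=sigma2,
        lam=lam_val,
        c=c,
        fitted=fitted,
        loo_errors=e_loo,
        loo_sse=float(e_loo @ e_loo),
        sigma_hat2=sigma_hat2,
        K=K,
        evals=evals,
        evecs=Q,
    )


@dataclass
class MarginalEffects:
    """Pointwise derivatives of the fitted surface in original units."""

    names: list[str]
    pointwise: np.ndarray  # n x D
    avg: np.ndarray
    se_avg: np.ndarray
    p_avg: np.ndarray
    quantiles: pd.DataFrame  # index covariate, columns p25/p50/p75


def pointwise_derivatives(krls_fit: KRLSFit, design: StandardizedDesign) -> MarginalEffects:
    """Closed-form pointwise partial derivatives, rescaled to original units.

    In standardized space d yhat_i/d x_d = -(2/sigma2) sum_j c_j K_ij
    (x_id - x_jd); the original-unit effect multiplies by sd_y / sd_xd.
    The average effect per covariate is linear in c, so its standard error
    follows from cov(c) = sigma_hat^2 (K + lambda I)^{-2} by the delta
    method; p-values are two-sided normal.
    """
    X, K, c = design.X, krls_fit.K, krls_fit.c
    n, D = X.shape
    s2 = krls_fit.sigma2
    Kc = K @ c
    # sum_j c_j K_ij x_jd, all d at once
    KcX = K @ (c[:, None] * X)
    deriv_std = -(2.0 / s2) * (X * Kc[:, None] - KcX)
    scale = design.y_sd / design.x_sd  # per covariate
    pointwise = deriv_std * scale[None, :]

    avg = pointwise.mean(axis=0)
    # weight vector of the average standardized derivative as a linear form in c
    colsum = K.sum(axis=0)
    evals, Q = krls_fit.evals, krls_fit.evecs
    se = np.empty(D)
    for d in range(D):
        w = -(2.0 / s2) / n * (K @ X[:, d] - X[:, d] * colsum)
        Qtw = Q.T @ w
        var_std = krls_fit.sigma_hat2 * float(np.sum((Qtw / (evals + krls_fit.lam)) ** 2))
        se[d] = np.sqrt(var_std) * scale[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, avg / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    q = np.quantile(pointwise, [0.25, 0.5, 0.75], axis=0, method="linear")
    quantiles = pd.DataFrame(
        q.T, index=design.names, columns=["p25", "p50", "p75"]
    )
    return MarginalEffects(
        names=list(design.names),
        pointwise=pointwise,
        avg=avg,
        se_avg=se,
        p_avg=p,
        quantiles=quantiles,
    )


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize_effects(effects: MarginalEffects) -> pd.DataFrame:
    """One row per covariate: avg, P25, P50, P75, se, p, stars.

    Quantiles use linear interpolation between closest ranks.
    """
    rows = []
    for d, name in enumerate(effects.names):
        rows.append(
            {
                "covariate": name,
                "avg": effects.avg[d],
                "p25": effects.quantiles.loc[name, "p25"],
                "p50": effects.quantiles.loc[name, "p50"],
                "p75": effects.quantiles.loc[name, "p75"],
                "se": effects.se_avg[d],
                "p_value": effects.p_avg[d],
                "stars": significance_stars(effects.p_avg[d]),
            }
        )
    return pd.DataFrame(rows)


def best_subset(
    X_candidates: pd.DataFrame, y: np.ndarray, max_size: int | None = None
) -> tuple[str, ...]:
    """Exhaustive best-subset covariate selection by leave-one-out SSE.

    Enumerates every non-empty subset of the candidate columns up to
    ``max_size``, fits KRLS to each, and returns the subset with the lowest
    LOO SSE; ties prefer smaller subsets, then lexicographic column order.
    Limited to 15 candidates (2^15 fits).
    """
    names = list(X_candidates.columns)
    if len(names) > 15:
        raise ValueError(
            f"{len(names)} candidates exceed the exhaustive-search bound of 15; "
            "pre-screen the covariates first"
        )
    if max_size is None:
        max_size = len(names)
    y = np.asarray(y, dtype=float)
    best: tuple[float, int, tuple[str, ...]] | None = None
    for size in range(1, max_size + 1):
        for combo in combinations(names, size):
            design = standardize(X_candidates[list(combo)].to_numpy(), y, names=list(combo))
            f = fit(design)
            key = (f.loo_sse, size, combo)
            if best is None or key < best:
                best = key
    assert best is not None
    return best[2]
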