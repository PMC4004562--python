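"""Cross-study pooling, heterogeneity statistics, and the nonlinearity test.

Per-study trend coefficients are combined by inverse-variance fixed-effect
pooling or DerSimonian–Laird random-effects pooling (moment estimator of
the between-study variance τ²).  For the two-coefficient spline model the
same machinery runs multivariately: the Cochran statistic generalizes to
``Q = Σ (β_i − β_FE)' C_i⁻¹ (β_i − β_FE)`` with ``df = p(k−1)``, and a
single scalar τ² (moment-matched on that Q) is added to each coefficient's
variance — five studies cannot support an unstructured between-study
covariance.

Heterogeneity is summarized by I² = max(0, 100·(Q − df)/Q) with the
Higgins–Thompson test-based confidence interval computed on the ln H
scale.  Departure from log-linearity is judged by a Wald test that the
pooled second spline coefficient is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trend_models import TrendFit


class InsufficientStudiesError(ValueError):
    pass


class UndefinedTestError(ValueError):
    pass


@dataclass(frozen=True)
class PooledResult:
    """Pooled dose-response coefficients with heterogeneity diagnostics."""

    model: str  # "linear" | "spline"
    method: str  # "fixed" | "random"
    beta: np.ndarray
    cov_beta: np.ndarray
    tau2: float
    Q: float
    df: int
    p_Q: float
    i2: float
    i2_ci: tuple[float, float] | None
    k: int
    p_nonlinearity: float | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


def _stack(fits: list[TrendFit]):
    if len(fits) < 2:
        raise InsufficientStudiesError(f"need >=2 studies, got {len(fits)}")
    models = {f.model for f in fits}
    dims = {f.beta.shape[0] for f in fits}
    if len(models) != 1 or len(dims) != 1:
        raise ValueError("fits must share one model and coefficient dimension")
    betas = [np.atleast_1d(f.beta) for f in fits]
    covs = [np.atleast_2d(f.cov_beta) for f in fits]
    return models.pop(), betas, covs


def _fixed_effect(betas, covs):
    W = [np.linalg.inv(c) for c in covs]
    S = sum(W)
    cov = np.linalg.inv(S)
    cov = 0.5 * (cov + cov.T)
    beta = cov @ sum(w @ b for w, b in zip(W, betas))
    return beta, cov, W, S


def _cochran_q(betas, covs, beta_fe):
    return float(
        sum(
            (b - beta_fe) @ np.linalg.inv(c) @ (b - beta_fe)
            for b, c in zip(betas, covs)
        )
    )


def heterogeneity_ci(Q: float, k: int, ci_level: float = 0.95):
    """I² point estimate with the Higgins–Thompson test-based CI.

    ``H = max(1, sqrt(Q/(k−1)))``; the standard error of ln H uses the
    large-Q expression when ``Q > k`` and the small-Q expression otherwise.
    The interval is built on the ln H scale around the truncated H, then
    mapped through ``I² = 100·(H²−1)/H²`` and truncated to [0, 100].
    Returns ``(i2, (lo, hi) or None)`` — the CI is undefined for k = 2 with
    small Q.
    """
    if k < 2:
        raise InsufficientStudiesError("heterogeneity needs >=2 studies")
    df = k - 1
    H = math.sqrt(max(Q, 0.0) / df)
    H_trunc = max(1.0, H)
    i2 = 100.0 * (H_trunc**2 - 1.0) / H_trunc**2

    if Q > k:
        se_lnH = 0.5 * (math.log(Q) - math.log(df)) / (
            math.sqrt(2.0 * Q) - math.sqrt(2.0 * k - 3.0)
        )
    elif k > 2:
        se_lnH = math.sqrt(
            (1.0 / (2.0 * (k - 2.0))) * (1.0 - 1.0 / (3.0 * (k - 2.0) ** 2))
        )
    else:
        return i2, None  # k = 2, Q <= k: no usable variance formula

    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    lnH = math.log(H_trunc)
    H_lo = max(1.0, math.exp(lnH - z * se_lnH))
    H_hi = max(1.0, math.exp(lnH + z * se_lnH))
    to_i2 = lambda h: min(100.0, max(0.0, 100.0 * (h**2 - 1.0) / h**2))
    return i2, (to_i2(H_lo), to_i2(H_hi))


def pool_fixed(fits: list[TrendFit], ci_level: float = 0.95) -> PooledResult:
    """Inverse-variance fixed-effect pooling (multivariate for splines)."""
    model, betas, covs = _stack(fits)
    k, p = len(fits), betas[0].shape[0]
    beta, cov, W, S = _fixed_effect(betas, covs)
    Q = _cochran_q(betas, covs, beta)
    df = p * (k - 1)
    p_Q = float(stats.chi2.sf(Q, df))
    i2, i2_ci = heterogeneity_ci(Q, k if p == 1 else df + 1, ci_level)
    return PooledResult(
        model=model,
        method="fixed",
        beta=beta,
        cov_beta=cov,
        tau2=0.0,
        Q=Q,
        df=df,
        p_Q=p_Q,
        i2=i2,
        i2_ci=i2_ci,
        k=k,
    )


def pool_random(fits: list[TrendFit], ci_level: float = 0.95) -> PooledResult:
    """DerSimonian–Laird random-effects pooling.

    Univariate: ``τ² = max(0, (Q − df) / (Σw − Σw²/Σw))`` with fixed-effect
    weights ``w_i = 1/var_i``.  Multivariate (spline): the same moment
    construction with matrix weights, ``denom = Σ tr(W_i) − tr(S⁻¹ Σ W_i²)``,
    and the scalar τ² added to every coefficient's variance.  With τ² = 0
    the result equals :func:`pool_fixed` exactly.
    """
    model, betas, covs = _stack(fits)
    k, p = len(fits), betas[0].shape[0]
    beta_fe, cov_fe, W, S = _fixed_effect(betas, covs)
    Q = _cochran_q(betas, covs, beta_fe)
    df = p * (k - 1)

    Sinv = np.linalg.inv(S)
    denom = float(sum(np.trace(w) for w in W) - np.trace(Sinv @ sum(w @ w for w in W)))
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0

    covs_re = [c + tau2 * np.eye(p) for c in covs]
    beta, cov, _, _ = _fixed_effect(betas, covs_re)

    p_Q = float(stats.chi2.sf(Q, df))
    i2, i2_ci = heterogeneity_ci(Q, k if p == 1 else df + 1, ci_level)
    return PooledResult(
        model=model,
        method="random",
        beta=beta,
        cov_beta=cov,
        tau2=tau2,
        Q=Q,
        df=df,
        p_Q=p_Q,
        i2=i2,
        i2_ci=i2_ci,
        k=k,
    )


def nonlinearity_test(pooled_spline: PooledResult) -> float:
    """Two-sided Wald p-value for the pooled second spline coefficient = 0.

    A small p indicates departure from a log-linear dose-response.
    """
    if pooled_spline.model != "spline" or pooled_spline.beta.shape[0] != 2:
        raise UndefinedTestError("nonlinearity test requires a pooled spline fit")
    var = float(pooled_spline.cov_beta[1, 1])
    if not var > 0 or not math.isfinite(var):
        raise UndefinedTestError("degenerate variance for the second spline term")
    z = float(pooled_spline.beta[1]) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))
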