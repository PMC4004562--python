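"""Publication-bias diagnostics and leave-one-out sensitivity analysis.

Small-study effects are probed two ways on the per-study linear slopes:

* **Egger regression** — ordinary least squares of the standardized effect
  (slope/SE) on precision (1/SE); a nonzero intercept suggests funnel-plot
  asymmetry.  Two-sided t-test with k − 2 degrees of freedom.
* **Begg rank correlation** — Kendall's tau between the variance-stabilized
  effect deviations from the fixed-effect mean and the variances, with the
  standard continuity correction and tie-adjusted variance in the normal
  approximation.

Both tests are underpowered at the five-study scale typical of this
literature; reports carry k alongside the p-values.  Leave-one-out
re-pools the remaining studies after omitting each in turn, expressed as
an RR per dose increment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .meta_pooling import pool_fixed, pool_random
from .trend_models import TrendFit, per_increment

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BiasReport:
    egger_intercept: float
    egger_se: float
    egger_p: float
    begg_tau: float
    begg_p: float
    k: int
    funnel: list[tuple[str, float, float]]  # (study_id, effect, se)


@dataclass(frozen=True)
class LooRow:
    omitted: str
    rr: float
    ci_low: float
    ci_high: float


def _linear_effects(fits: list[TrendFit]):
    effects = np.array([float(f.beta[0]) for f in fits])
    variances = np.array([float(f.cov_beta[0, 0]) for f in fits])
    if np.any(variances <= 0):
        raise ValueError("non-positive slope variance")
    return effects, variances


def egger_test(fits: list[TrendFit]) -> tuple[float, float, float]:
    """Egger asymmetry test: OLS of SND on precision, t-test on the intercept.

    Returns ``(intercept, se, two-sided p)``.  Closed-form simple linear
    regression; degenerate when all precisions coincide.
    """
    if len(fits) < 3:
        raise ValueError("Egger test needs >=3 studies")
    effects, variances = _linear_effects(fits)
    se = np.sqrt(variances)
    y = effects / se  # standardized effects
    x = 1.0 / se  # precisions
    k = len(y)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 1e-30 * float(np.sum(x**2)):
        raise ValueError("all precisions equal: Egger regression is singular")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    s2 = float(np.sum(resid**2)) / (k - 2)
    se_int = math.sqrt(s2 * (1.0 / k + x.mean() ** 2 / sxx))
    if se_int == 0.0:
        return intercept, 0.0, 1.0 if intercept == 0.0 else 0.0
    t = intercept / se_int
    p = float(2.0 * stats.t.sf(abs(t), k - 2))
    return intercept, se_int, p


def begg_test(fits: list[TrendFit]) -> tuple[float, float]:
    """Begg–Mazumdar rank correlation test.

    Deviations from the fixed-effect mean are variance-stabilized,
    ``(β_i − β_FE)/sqrt(var_i − var_FE)``, then Kendall-correlated with the
    variances by exhaustive pair counting.  The normal approximation uses
    the tie-adjusted score variance and a continuity correction
    (|score| reduced by 1).  Returns ``(tau, p)``.
    """
    if len(fits) < 3:
        raise ValueError("Begg test needs >=3 studies")
    effects, variances = _linear_effects(fits)
    w = 1.0 / variances
    var_fe = 1.0 / w.sum()
    beta_fe = float(np.sum(w * effects) * var_fe)
    spread = variances - var_fe
    floor = 1e-12 * variances
    if np.any(spread <= 0):
        log.warning("Begg test: var_i <= var_FE for some study; flooring deviate scale")
    spread = np.maximum(spread, floor)
    dev = (effects - beta_fe) / np.sqrt(spread)

    k = len(dev)
    score = 0
    for i in range(k):
        for j in range(i + 1, k):
            score += int(np.sign(dev[j] - dev[i]) * np.sign(variances[j] - variances[i]))

    def tie_term(vals):
        _, counts = np.unique(vals, return_counts=True)
        return float(sum(t * (t - 1) * (2 * t + 5) for t in counts))

    n_pairs = k * (k - 1) / 2
    tau = score / n_pairs
    var_score = (
        k * (k - 1) * (2 * k + 5) - tie_term(dev) - tie_term(variances)
    ) / 18.0
    if var_score <= 0:
        return tau, 1.0
    z = max(abs(score) - 1.0, 0.0) / math.sqrt(var_score)
    p = float(2.0 * stats.norm.sf(z))
    return float(tau), p


def funnel_table(fits: list[TrendFit]) -> list[tuple[str, float, float]]:
    """(study_id, slope, se) rows for external funnel plotting."""
    effects, variances = _linear_effects(fits)
    return [
        (f.study_id, float(e), float(math.sqrt(v)))
        for f, e, v in zip(fits, effects, variances)
    ]


def leave_one_out(
    fits: list[TrendFit],
    increment: float = 5.0,
    ci_level: float = 0.95,
    method: str = "random",
) -> list[LooRow]:
    """Re-pool after omitting each study in turn; RR per ``increment`` U/L.

    Row order follows the input study order regardless of how the list is
    permuted between calls (rows are keyed by the omitted study).
    """
    if len(fits) < 3:
        raise ValueError("leave-one-out needs >=3 studies")
    pool = pool_random if method == "random" else pool_fixed
    rows = []
    for i, f in enumerate(fits):
        rest = fits[:i] + fits[i + 1 :]
        pooled = pool(rest, ci_level=ci_level)
        rr, lo, hi = per_increment(
            float(pooled.beta[0]), float(pooled.cov_beta[0, 0]), increment, ci_level
        )
        rows.append(LooRow(omitted=f.study_id, rr=rr, ci_low=lo, ci_high=hi))
    return rows


def bias_report(fits: list[TrendFit]) -> BiasReport:
    intercept, se, p_e = egger_test(fits)
    tau, p_b = begg_test(fits)
    return BiasReport(
        egger_intercept=intercept,
        egger_se=se,
        egger_p=p_e,
        begg_tau=tau,
        begg_p=p_b,
        k=len(fits),
        funnel=funnel_table(fits),
    )
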