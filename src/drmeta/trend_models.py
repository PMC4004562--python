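"""Per-study GLS dose-response models: linear trend and restricted cubic spline.

Within each study the adjusted log-RRs ``L`` (non-reference categories) are
regressed on dose contrasts ``X`` by generalized least squares with the
reconstructed covariance ``C``::

    beta = (X' C^-1 X)^-1 X' C^-1 L,    cov(beta) = (X' C^-1 X)^-1

For the linear model ``X`` has one column, ``dose_i − dose_ref``.  For the
nonlinear model the dose enters through a 3-knot restricted cubic spline
(Harrell basis): a linear term plus one cubic term that is zero below the
first knot and exactly linear beyond the last, so the fitted curve stays
linear in the tails.  Knots sit at weighted percentiles of the pooled
category-dose distribution, weights being category totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .gl_reconstruction import LogRRVector
from .study_io import StudyRecord


class DegenerateKnotsError(ValueError):
    pass


class RankError(ValueError):
    """Design/covariance combination cannot identify the coefficients."""


@dataclass(frozen=True)
class SplineSpec:
    """Three strictly increasing knots (ALT U/L) for the restricted cubic
    spline; the basis has dimension 2 (linear + one nonlinear term)."""

    knots: tuple[float, float, float]

    def __post_init__(self) -> None:
        k1, k2, k3 = self.knots
        if not (k1 < k2 < k3):
            raise DegenerateKnotsError(f"knots {self.knots} not strictly increasing")


@dataclass(frozen=True)
class TrendFit:
    """Per-study (or pooled) dose-response coefficients on the log-RR/U/L scale."""

    study_id: str
    stratum_id: str
    model: str  # "linear" | "spline"
    beta: np.ndarray
    cov_beta: np.ndarray
    reference_dose: float

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


@dataclass(frozen=True)
class CurvePoint:
    dose: float
    rr: float
    ci_low: float
    ci_high: float


def weighted_quantile(values, weights, q) -> np.ndarray:
    """Weighted empirical quantile with linear interpolation.

    Uses plotting positions ``p_k = (C_k − w_k) / (W − w_k)`` on the
    cumulative-weight scale (ties aggregated first), which reduces to the
    standard linear-interpolation quantile for equal weights and is
    invariant to duplicating the whole sample.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    order = np.argsort(values)
    v, w = values[order], weights[order]
    uv, inv = np.unique(v, return_inverse=True)
    uw = np.zeros_like(uv)
    np.add.at(uw, inv, w)
    if len(uv) == 1:
        return np.full(np.shape(q), uv[0])
    cum = np.cumsum(uw)
    W = cum[-1]
    p = (cum - uw) / (W - uw)
    return np.interp(q, p, uv)


def place_knots(
    studies: list[StudyRecord],
    percentiles: tuple[float, float, float] = (0.25, 0.50, 0.75),
) -> SplineSpec:
    """Knots at weighted percentiles of the pooled category doses.

    Every category of every study contributes its assigned dose, weighted
    by its participant total (or person-time), so large cohorts dominate
    the placement — a proxy for the pooled exposure distribution.
    """
    doses, weights = [], []
    for s in studies:
        for c in s.categories:
            if c.dose_assigned is None:
                raise ValueError(
                    f"study {s.study_id}: dose not assigned for {c.label!r}"
                )
            doses.append(c.dose_assigned)
            weights.append(c.total)
    knots = weighted_quantile(doses, weights, list(percentiles))
    if not (knots[0] < knots[1] < knots[2]):
        raise DegenerateKnotsError(
            f"percentiles {percentiles} give non-distinct knots {tuple(knots)}"
        )
    return SplineSpec(knots=tuple(float(k) for k in knots))


def rcs_basis(dose, spec: SplineSpec):
    """Harrell restricted-cubic-spline basis (s1, s2) at one or many doses.

    ``s1`` is the dose itself; ``s2`` is the single nonlinear term for 3
    knots, scaled by ``(k3 − k1)²`` so its coefficient lives on a slope-like
    scale.  ``s2 = 0`` below the first knot and grows linearly beyond the
    last knot.
    """
    d = np.asarray(dose, dtype=float)
    k1, k2, k3 = spec.knots

    def pc3(x):  # positive part, cubed
        return np.clip(x, 0.0, None) ** 3

    s2 = (
        pc3(d - k1)
        - pc3(d - k2) * (k3 - k1) / (k3 - k2)
        + pc3(d - k3) * (k2 - k1) / (k3 - k2)
    ) / (k3 - k1) ** 2
    return d, s2


def _design_matrix(doses: np.ndarray, ref_dose: float, model: str, spec: SplineSpec | None) -> np.ndarray:
    if model == "linear":
        return (doses - ref_dose)[:, None]
    if model == "spline":
        if spec is None:
            raise ValueError("spline model requires a SplineSpec")
        s1, s2 = rcs_basis(doses, spec)
        r1, r2 = rcs_basis(ref_dose, spec)
        return np.column_stack([s1 - r1, s2 - r2])
    raise ValueError(f"unknown model {model!r}")


def gls_fit(
    study: StudyRecord,
    lrr: LogRRVector,
    model: str = "linear",
    spec: SplineSpec | None = None,
) -> TrendFit:
    """Generalized least-squares trend fit for one study.

    Solves via Cholesky of ``C``; raises :class:`RankError` when
    ``X' C^-1 X`` is numerically singular (e.g. a spline model with fewer
    than 3 non-reference categories).
    """
    if lrr.C is None:
        raise ValueError("lrr must carry a full covariance matrix")
    doses = np.array(
        [c.dose_assigned for c in study.categories if not c.is_reference],
        dtype=float,
    )
    ref_dose = study.categories[study.reference_index].dose_assigned
    if ref_dose is None or np.any(np.equal(doses, None)):
        raise ValueError("all doses must be assigned before fitting")
    if model == "spline" and len(doses) < 3:
        raise RankError(
            f"study {study.study_id}: spline model needs >=3 non-reference "
            f"categories, got {len(doses)}"
        )
    X = _design_matrix(doses, float(ref_dose), model, spec)
    cho = linalg.cho_factor(lrr.C, lower=True)
    CiX = linalg.cho_solve(cho, X)
    CiL = linalg.cho_solve(cho, lrr.L)
    XtCiX = X.T @ CiX
    if 1.0 / np.linalg.cond(XtCiX) < 1e-12:
        raise RankError(
            f"study {study.study_id}: singular normal matrix (condition "
            f"number {np.linalg.cond(XtCiX):.3e})"
        )
    cov = np.linalg.inv(XtCiX)
    cov = 0.5 * (cov + cov.T)
    beta = cov @ (X.T @ CiL)
    return TrendFit(
        study_id=study.study_id,
        stratum_id=study.stratum_id,
        model=model,
        beta=np.atleast_1d(beta),
        cov_beta=np.atleast_2d(cov),
        reference_dose=float(ref_dose),
    )


def combine_strata(fits: list[TrendFit]) -> TrendFit:
    """Fixed-effect (inverse-variance) combination of strata of one study.

    Multivariate for the spline model: ``cov = (Σ cov_j⁻¹)⁻¹``,
    ``beta = cov · Σ cov_j⁻¹ beta_j``.  A single stratum is returned as-is.
    """
    if not fits:
        raise ValueError("no fits to combine")
    if len(fits) == 1:
        return fits[0]
    models = {f.model for f in fits}
    if len(models) != 1:
        raise ValueError(f"cannot combine mixed models across strata: {models}")
    dims = {f.beta.shape[0] for f in fits}
    if len(dims) != 1:
        raise ValueError("strata have incompatible coefficient dimensions")
    Wsum = np.zeros((dims.pop(),) * 2)
    Wb = np.zeros(Wsum.shape[0])
    for f in fits:
        W = np.linalg.inv(f.cov_beta)
        Wsum += W
        Wb += W @ f.beta
    cov = np.linalg.inv(Wsum)
    cov = 0.5 * (cov + cov.T)
    beta = cov @ Wb
    return TrendFit(
        study_id=fits[0].study_id,
        stratum_id="combined",
        model=fits[0].model,
        beta=beta,
        cov_beta=cov,
        reference_dose=fits[0].reference_dose,
    )


def predict_curve(
    beta: np.ndarray,
    cov_beta: np.ndarray,
    reference_dose: float,
    grid,
    spec: SplineSpec | None = None,
    ci_level: float = 0.95,
) -> list[CurvePoint]:
    """Pointwise RR curve with delta-method CI, anchored at RR = 1 at the
    reference dose.

    ``log-RR(d) = x(d)' beta`` with ``x(d) = basis(d) − basis(reference)``;
    variance ``x(d)' cov x(d)``.  Works for both the 1-parameter linear
    model and the 2-parameter spline.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    cov_beta = np.atleast_2d(np.asarray(cov_beta, dtype=float))
    model = "linear" if beta.shape[0] == 1 else "spline"
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    grid = np.asarray(grid, dtype=float)
    X = _design_matrix(grid, reference_dose, model, spec)
    lp = X @ beta
    var = np.einsum("ij,jk,ik->i", X, cov_beta, X)
    se = np.sqrt(np.maximum(var, 0.0))
    out = []
    for d, m, s in zip(grid, lp, se):
        out.append(
            CurvePoint(
                dose=float(d),
                rr=math.exp(m),
                ci_low=math.exp(m - z * s),
                ci_high=math.exp(m + z * s),
            )
        )
    return out


def per_increment(
    beta: float, var: float, increment: float = 5.0, ci_level: float = 0.95
) -> tuple[float, float, float]:
    """Rescale a per-U/L linear log-RR slope to an RR per ``increment`` U/L.

    Returns ``(rr, ci_low, ci_high)`` with
    ``rr = exp(increment·beta)`` and normal-theory CI
    ``exp(increment·(beta ± z·se))``.
    """
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    se = math.sqrt(max(var, 0.0))
    return (
        math.exp(increment * beta),
        math.exp(increment * (beta - z * se)),
        math.exp(increment * (beta + z * se)),
    )
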