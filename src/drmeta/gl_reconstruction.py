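"""Greenland–Longnecker covariance reconstruction from category margins.

Category-specific relative risks within one study share a reference group,
so their log-RRs are correlated; ignoring the correlation biases trend
standard errors.  The remedy is to reconstruct a table of *pseudo-counts*
(fitted cases ``a_i`` per category) that is exactly consistent with the
reported adjusted log-RRs ``L_i`` while conserving the study's total case
margin.  Each non-reference ``a_i`` is an explicit function of the
reference cell ``a_0`` given ``L_i`` and the design's crude-RR formula, so
the margin constraint reduces to a one-dimensional root-finding problem in
``a_0``, solved here by bisection (guaranteed bracketing).

The fitted reference cell then yields the off-diagonal covariance between
any two log-RRs:

* cumulative incidence:  ``cov = 1/a_0 − 1/n_0``
* incidence rate:        ``cov = 1/a_0``
* case-control:          ``cov = 1/a_0 + 1/b_0``

Reported variances (from the published CI half-widths) are kept on the
diagonal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .study_io import StudyRecord

log = logging.getLogger(__name__)


class InvalidCIError(ValueError):
    pass


class InfeasibleMarginsError(ValueError):
    """No reference cell in (0, total cases) satisfies the margin."""


class NonConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"pseudo-count fit did not converge in {max_iter} iterations "
            f"(margin residual {residual:.3e})"
        )


class ConditioningError(ValueError):
    """Reconstructed covariance is not positive definite."""


@dataclass(frozen=True)
class PseudoTable:
    """Fitted pseudo-counts for one study (reference cell first invariant).

    ``a`` are fitted cases per category (in category order), ``b`` the
    complementary cells: non-cases for cumulative-incidence/case-control,
    person-time for incidence-rate designs.
    """

    a: np.ndarray
    b: np.ndarray
    reference_index: int
    design: str

    @property
    def a0(self) -> float:
        return float(self.a[self.reference_index])

    @property
    def b0(self) -> float:
        return float(self.b[self.reference_index])


@dataclass(frozen=True)
class LogRRVector:
    """Non-reference log-RRs with reported variances and full covariance."""

    L: np.ndarray
    V: np.ndarray
    C: np.ndarray | None = None
    indices: tuple[int, ...] = ()  # category indices of the entries


def log_rr_vector(study: StudyRecord, ci_level: float = 0.95) -> LogRRVector:
    """Log-RRs and reported variances for the non-reference categories.

    The variance comes from the log-scale CI half-width:
    ``V_i = ((ln ci_high − ln ci_low) / (2 z))²`` with ``z`` the
    standard-normal quantile for ``ci_level``.
    """
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    L, V, idx = [], [], []
    for i, c in enumerate(study.categories):
        if c.is_reference:
            continue
        if c.ci_high <= c.ci_low:
            raise InvalidCIError(
                f"study {study.study_id}, category {c.label!r}: "
                f"ci_high {c.ci_high} <= ci_low {c.ci_low}"
            )
        L.append(math.log(c.rr))
        V.append(((math.log(c.ci_high) - math.log(c.ci_low)) / (2.0 * z)) ** 2)
        idx.append(i)
    return LogRRVector(L=np.asarray(L), V=np.asarray(V), indices=tuple(idx))


def _fitted_cases(a0: float, study: StudyRecord, L_by_index: dict[int, float]) -> np.ndarray:
    """All fitted cases as an explicit function of the reference cell a0."""
    ref = study.reference_index
    cats = study.categories
    n = np.array([c.total for c in cats], dtype=float)
    a = np.empty(len(cats))
    a[ref] = a0
    for i, c in enumerate(cats):
        if i == ref:
            continue
        rr = math.exp(L_by_index[i])
        if study.design in ("cumulative_incidence", "incidence_rate"):
            # crude RR = (a_i/n_i) / (a_0/n_0)
            a[i] = rr * a0 * n[i] / n[ref]
        elif study.design == "case_control":
            # crude OR = a_i b_0 / (a_0 b_i), b_i = n_i - a_i
            b0 = n[ref] - a0
            r = rr * a0 / b0
            a[i] = n[i] * r / (1.0 + r)
        else:
            raise ValueError(f"unknown design {study.design!r}")
    return a


def fit_pseudo_counts(
    study: StudyRecord,
    lrr: LogRRVector,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> PseudoTable:
    """Fit pseudo-counts matching the adjusted log-RRs and the case margin.

    Bisection on the reference cell ``a_0`` over its feasible interval; the
    margin residual ``Σ a_i − A`` is strictly increasing in ``a_0``, so the
    bracket is guaranteed.  Categories with zero observed cases get a 0.5
    continuity addition (logged) before the total-case margin is formed.
    """
    cats = study.categories
    ref = study.reference_index
    cases = np.array([c.cases for c in cats], dtype=float)
    if np.any(cases == 0):
        log.warning(
            "study %s/%s: zero-case category; adding 0.5 continuity correction",
            study.study_id,
            study.stratum_id,
        )
        cases = cases + 0.5 * (cases == 0)
    A = float(cases.sum())
    n = np.array([c.total for c in cats], dtype=float)
    L_by_index = dict(zip(lrr.indices, lrr.L))

    lo = 1e-9 * A
    hi = A
    if study.design in ("cumulative_incidence", "case_control"):
        hi = min(hi, n[ref] * (1.0 - 1e-12))

    def resid(a0: float) -> float:
        return float(_fitted_cases(a0, study, L_by_index).sum() - A)

    r_lo, r_hi = resid(lo), resid(hi)
    if r_lo > 0 or r_hi < 0:
        raise InfeasibleMarginsError(
            f"study {study.study_id}/{study.stratum_id}: no reference cell in "
            f"(0, {hi:.6g}) satisfies the total-case margin "
            f"(residuals {r_lo:.3e}, {r_hi:.3e})"
        )

    a0 = 0.5 * (lo + hi)
    r = resid(a0)
    it = 0
    while abs(r) > tol * max(1.0, A):
        if r > 0:
            hi = a0
        else:
            lo = a0
        a0 = 0.5 * (lo + hi)
        r = resid(a0)
        it += 1
        if it >= max_iter:
            raise NonConvergenceError(abs(r), max_iter)

    a = _fitted_cases(a0, study, L_by_index)
    if study.design == "incidence_rate":
        b = n.copy()  # person-time is the complementary margin
    else:
        b = n - a
    table = PseudoTable(a=a, b=b, reference_index=ref, design=study.design)
    _check_pseudo(table, A, n, study)
    return table


def _check_pseudo(t: PseudoTable, A: float, n: np.ndarray, study: StudyRecord) -> None:
    if abs(t.a.sum() - A) > 1e-8 * max(1.0, A):
        raise NonConvergenceError(abs(t.a.sum() - A), 0)
    if np.any(t.a <= 0):
        raise InfeasibleMarginsError(
            f"study {study.study_id}: non-positive fitted pseudo-cases"
        )
    if study.design == "cumulative_incidence" and np.any(t.a > n + 1e-8):
        raise InfeasibleMarginsError(
            f"study {study.study_id}: fitted cases exceed category totals"
        )


def covariance_matrix(pseudo: PseudoTable, lrr: LogRRVector) -> LogRRVector:
    """Full covariance of the log-RR vector from the fitted reference cell.

    Diagonal keeps the reported variances; a common off-diagonal term comes
    from the shared reference cell.  Positive definiteness is verified via
    Cholesky.
    """
    m = len(lrr.L)
    if pseudo.design == "cumulative_incidence":
        off = 1.0 / pseudo.a0 - 1.0 / (pseudo.a0 + pseudo.b0)
    elif pseudo.design == "incidence_rate":
        off = 1.0 / pseudo.a0
    elif pseudo.design == "case_control":
        off = 1.0 / pseudo.a0 + 1.0 / pseudo.b0
    else:
        raise ValueError(f"unknown design {pseudo.design!r}")
    C = np.full((m, m), off)
    np.fill_diagonal(C, lrr.V)
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(
            "reconstructed covariance is not positive definite; review the "
            "study's counts and confidence intervals"
        ) from exc
    return LogRRVector(L=lrr.L, V=lrr.V, C=C, indices=lrr.indices)


def study_covariance(
    study: StudyRecord,
    ci_level: float = 0.95,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> LogRRVector:
    """Convenience: log-RR vector with full covariance for one study.

    Falls back to a diagonal covariance (independent log-RRs) with a
    prominent warning when category counts are unusable — sources normally
    report them, so this path indicates degraded inputs.
    """
    lrr = log_rr_vector(study, ci_level)
    has_counts = all(c.total > 0 for c in study.categories) and all(
        c.cases >= 0 for c in study.categories
    ) and sum(c.cases for c in study.categories) > 0
    if not has_counts:
        log.warning(
            "study %s/%s: missing category counts; using DIAGONAL covariance "
            "(independence approximation)",
            study.study_id,
            study.stratum_id,
        )
        return LogRRVector(L=lrr.L, V=lrr.V, C=np.diag(lrr.V), indices=lrr.indices)
    pseudo = fit_pseudo_counts(study, lrr, tol=tol, max_iter=max_iter)
    return covariance_matrix(pseudo, lrr)
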