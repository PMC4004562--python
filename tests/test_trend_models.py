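import math

import numpy as np
import pytest

from drmeta.gl_reconstruction import LogRRVector, study_covariance
from drmeta.trend_models import (
    DegenerateKnotsError,
    RankError,
    SplineSpec,
    TrendFit,
    combine_strata,
    gls_fit,
    per_increment,
    place_knots,
    predict_curve,
    rcs_basis,
    weighted_quantile,
)

from conftest import make_category, make_study


def _study_with_doses(doses, rrs, cis, totals=None, cases=None):
    totals = totals or [200] + [100] * (len(doses) - 1)
    cases = cases or [20] * len(doses)
    cats = [
        make_category("ref", None, None, doses[0], 1.0, 1.0, 1.0, cases[0], totals[0], True)
    ]
    for i, d in enumerate(doses[1:], 1):
        cats.append(
            make_category(f"c{i}", None, None, d, rrs[i - 1], cis[i - 1][0], cis[i - 1][1], cases[i], totals[i])
        )
    return make_study(cats)


# ---------------------------------------------------------------- knots


def test_knot_placement_matches_hand_quantiles():
    study = _study_with_doses(
        [5, 10, 15, 20],
        [1.2, 1.4, 1.6],
        [(1.0, 1.5), (1.1, 1.8), (1.2, 2.1)],
        totals=[100, 100, 100, 100],
    )
    spec = place_knots([study], (0.25, 0.50, 0.75))
    assert spec.knots == pytest.approx((8.75, 12.5, 16.25))


def test_knots_invariant_to_duplicating_studies():
    study = _study_with_doses(
        [5, 10, 15, 20], [1.2, 1.4, 1.6], [(1.0, 1.5), (1.1, 1.8), (1.2, 2.1)],
        totals=[100, 100, 100, 100],
    )
    one = place_knots([study])
    two = place_knots([study, study])
    assert two.knots == pytest.approx(one.knots)


def test_degenerate_knots_error():
    study = _study_with_doses([10, 10, 10], [1.2, 1.4], [(1.0, 1.5), (1.1, 1.8)])
    with pytest.raises(DegenerateKnotsError):
        place_knots([study])


def test_weighted_quantile_reduces_to_numpy_linear(rng):
    x = rng.normal(size=13)
    q = [0.1, 0.25, 0.5, 0.9]
    assert weighted_quantile(x, np.ones_like(x), q) == pytest.approx(
        np.quantile(x, q), rel=1e-12
    )


# ---------------------------------------------------------------- spline basis


def test_rcs_basis_zero_below_first_knot():
    spec = SplineSpec((10, 20, 30))
    for d in [0, 5, 9.99, 10]:
        assert rcs_basis(d, spec)[1] == 0.0


def test_rcs_basis_value_at_middle_knot():
    spec = SplineSpec((10, 20, 30))
    assert rcs_basis(20, spec)[1] == pytest.approx(2.5)  # 1000/400


def test_rcs_basis_linear_beyond_last_knot():
    spec = SplineSpec((10, 20, 30))
    s = lambda d: rcs_basis(d, spec)[1]
    assert s(40) - s(35) == pytest.approx(s(35) - s(30), rel=1e-9)
    # and strictly nonlinear between k1 and k3
    assert s(25) - s(20) != pytest.approx(s(20) - s(15), rel=1e-3)


# ---------------------------------------------------------------- GLS


def test_single_category_closed_form():
    study = _study_with_doses([0, 5], [math.exp(0.7)], [(1.0, 4.0)])
    lrr = LogRRVector(L=np.array([0.7]), V=np.array([0.04]), C=np.array([[0.04]]), indices=(1,))
    fit = gls_fit(study, lrr, model="linear")
    assert fit.beta[0] == pytest.approx(0.7 / 5.0)  # L / delta-dose
    assert fit.se[0] == pytest.approx(math.sqrt(0.04) / 5.0)


def test_exact_linear_log_rrs_recovered():
    slope = 0.03
    doses = [0.0, 5.0, 12.0, 20.0]
    L = np.array([slope * d for d in doses[1:]])
    lrr = LogRRVector(L=L, V=np.ones(3), C=np.eye(3), indices=(1, 2, 3))
    study = _study_with_doses(doses, np.exp(L), [(0.5, 9.0)] * 3)
    fit = gls_fit(study, lrr, model="linear")
    assert fit.beta[0] == pytest.approx(slope, abs=1e-14)


def test_gls_matches_textbook_matrix_oracle(three_cat_study):
    """2x2 closed-form GLS on the hand-solved covariance instance."""
    lrr = study_covariance(three_cat_study)
    fit = gls_fit(three_cat_study, lrr, model="linear")
    X = np.array([[15.0 - 6.0], [25.0 - 6.0]])
    Ci = np.linalg.inv(lrr.C)
    cov = np.linalg.inv(X.T @ Ci @ X)
    beta = cov @ X.T @ Ci @ lrr.L
    assert fit.beta[0] == pytest.approx(beta[0], abs=1e-10)
    assert fit.cov_beta[0, 0] == pytest.approx(cov[0, 0], abs=1e-10)


def test_gls_diagonal_equals_weighted_least_squares(rng):
    """With independent log-RRs, GLS collapses to WLS with weights 1/V."""
    for _ in range(10):
        m = int(rng.integers(3, 6))
        doses = np.sort(rng.uniform(5, 40, size=m + 1))
        L = rng.normal(0.02 * (doses[1:] - doses[0]), 0.1)
        V = rng.uniform(0.01, 0.2, size=m)
        lrr = LogRRVector(L=L, V=V, C=np.diag(V), indices=tuple(range(1, m + 1)))
        study = _study_with_doses(
            doses, np.exp(L), [(lo, hi) for lo, hi in zip(np.exp(L) * 0.5, np.exp(L) * 2)],
            totals=[100] * (m + 1), cases=[10] * (m + 1),
        )
        fit = gls_fit(study, lrr, model="linear")
        x = doses[1:] - doses[0]
        w = 1.0 / V
        beta_wls = np.sum(w * x * L) / np.sum(w * x * x)
        assert fit.beta[0] == pytest.approx(beta_wls, rel=1e-10)


def test_spline_needs_three_nonreference_categories():
    study = _study_with_doses([0, 5, 10], [1.1, 1.2], [(1.0, 1.3), (1.05, 1.4)])
    lrr = LogRRVector(
        L=np.log([1.1, 1.2]), V=np.array([0.01, 0.01]), C=np.eye(2) * 0.01,
        indices=(1, 2),
    )
    with pytest.raises(RankError):
        gls_fit(study, lrr, model="spline", spec=SplineSpec((2, 5, 8)))


def test_spline_with_null_second_term_matches_linear():
    """When the data are exactly linear, the spline fit finds beta2 = 0 and
    beta1 equal to the linear slope."""
    slope = 0.025
    doses = [6.0, 12.0, 20.0, 30.0, 40.0]
    L = np.array([slope * (d - doses[0]) for d in doses[1:]])
    lrr = LogRRVector(L=L, V=np.ones(4) * 0.01, C=np.eye(4) * 0.01, indices=(1, 2, 3, 4))
    study = _study_with_doses(doses, np.exp(L), [(0.5, 9.0)] * 4)
    spec = SplineSpec((10, 20, 30))
    fit = gls_fit(study, lrr, model="spline", spec=spec)
    lin = gls_fit(study, lrr, model="linear")
    assert fit.beta[1] == pytest.approx(0.0, abs=1e-12)
    assert fit.beta[0] == pytest.approx(lin.beta[0], abs=1e-12)


# ---------------------------------------------------------------- strata


def test_combine_strata_inverse_variance():
    f1 = TrendFit("s", "men", "linear", np.array([0.02]), np.array([[1e-4]]), 6.0)
    f2 = TrendFit("s", "women", "linear", np.array([0.03]), np.array([[1e-4]]), 6.0)
    out = combine_strata([f1, f2])
    assert out.beta[0] == pytest.approx(0.025)
    assert out.cov_beta[0, 0] == pytest.approx(5e-5)


def test_combine_single_stratum_identity():
    f1 = TrendFit("s", "all", "linear", np.array([0.02]), np.array([[1e-4]]), 6.0)
    assert combine_strata([f1]) is f1


def test_combine_identical_strata_halves_variance():
    f = TrendFit("s", "a", "spline", np.array([0.02, 0.001]),
                 np.array([[1e-4, 1e-6], [1e-6, 4e-5]]), 6.0)
    out = combine_strata([f, f])
    assert out.beta == pytest.approx(f.beta)
    assert out.cov_beta == pytest.approx(f.cov_beta / 2)


def test_combine_mixed_models_rejected():
    f1 = TrendFit("s", "a", "linear", np.array([0.02]), np.array([[1e-4]]), 6.0)
    f2 = TrendFit("s", "b", "spline", np.array([0.02, 0.0]), np.eye(2) * 1e-4, 6.0)
    with pytest.raises(ValueError, match="mixed models"):
        combine_strata([f1, f2])


# ---------------------------------------------------------------- curve


def test_curve_anchored_at_reference():
    pts = predict_curve(np.array([0.028]), np.array([[1e-5]]), 6.0, [6.0, 11.0])
    assert (pts[0].rr, pts[0].ci_low, pts[0].ci_high) == (1.0, 1.0, 1.0)


def test_linear_curve_exponentiates_slope():
    beta = math.log(1.14) / 5.0
    pts = predict_curve(np.array([beta]), np.array([[0.0]]), 6.0, [11.0])
    assert pts[0].rr == pytest.approx(1.14)


def test_curve_grid_permutation_invariance():
    spec = SplineSpec((10, 20, 30))
    beta = np.array([0.02, 0.005])
    cov = np.array([[1e-5, 1e-6], [1e-6, 4e-5]])
    grid = [8.0, 15.0, 25.0, 35.0]
    fwd = predict_curve(beta, cov, 6.0, grid, spec=spec)
    rev = predict_curve(beta, cov, 6.0, grid[::-1], spec=spec)
    for a, b in zip(fwd, rev[::-1]):
        assert (a.rr, a.ci_low, a.ci_high) == (b.rr, b.ci_low, b.ci_high)


def test_delta_method_ci_against_monte_carlo(rng):
    """Delta-method band equals the quantile-free lognormal band implied by
    simulating coefficients from their sampling distribution."""
    spec = SplineSpec((10, 20, 30))
    beta = np.array([0.02, 0.008])
    cov = np.array([[2e-5, 5e-6], [5e-6, 6e-5]])
    dose, ref = 25.0, 6.0
    pts = predict_curve(beta, cov, ref, [dose], spec=spec)
    draws = rng.multivariate_normal(beta, cov, size=1_000_000)
    s1, s2 = rcs_basis(dose, spec)
    r1, r2 = rcs_basis(ref, spec)
    x = np.array([s1 - r1, s2 - r2])
    lp = draws @ x
    mc_lo, mc_hi = np.exp(np.mean(lp) - 1.959964 * np.std(lp)), np.exp(
        np.mean(lp) + 1.959964 * np.std(lp)
    )
    assert pts[0].ci_low == pytest.approx(mc_lo, rel=5e-3)
    assert pts[0].ci_high == pytest.approx(mc_hi, rel=5e-3)


# ---------------------------------------------------------------- increments


def test_per_increment_null():
    assert per_increment(0.0, 0.0, 5.0) == pytest.approx((1.0, 1.0, 1.0))


def test_per_increment_reporting_convention():
    # slope chosen so RR per 5 U/L is 1.14 with upper bound 1.17
    beta = math.log(1.14) / 5.0
    se = math.log(1.17 / 1.14) / (5 * 1.959963984540054)
    rr, lo, hi = per_increment(beta, se**2, 5.0)
    assert rr == pytest.approx(1.14)
    assert hi == pytest.approx(1.17)


def test_doubling_increment_squares_rr():
    rr5, _, _ = per_increment(0.02, 1e-5, 5.0)
    rr10, _, _ = per_increment(0.02, 1e-5, 10.0)
    assert rr10 == pytest.approx(rr5**2, rel=1e-12)
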