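import math

import numpy as np
import pytest

from drmeta.gl_reconstruction import (
    InvalidCIError,
    LogRRVector,
    covariance_matrix,
    fit_pseudo_counts,
    log_rr_vector,
    study_covariance,
)

from conftest import make_category, make_study


def grid_search_a0(study, L, step=1e-4):
    """Brute-force oracle: scan the reference cell on a fine grid and pick
    the value minimizing the total-case margin residual."""
    from drmeta.gl_reconstruction import _fitted_cases

    A = sum(c.cases for c in study.categories)
    L_by_index = dict(
        zip([i for i, c in enumerate(study.categories) if not c.is_reference], L)
    )
    hi = min(A, study.categories[study.reference_index].total)
    grid = np.arange(step, hi, step)
    resid = np.array(
        [abs(_fitted_cases(a0, study, L_by_index).sum() - A) for a0 in grid]
    )
    return grid[int(np.argmin(resid))]


def crude_log_rr(study, a):
    """Design-specific crude log-RRs from fitted counts (independent check)."""
    ref = study.reference_index
    n = [c.total for c in study.categories]
    out = []
    for i, c in enumerate(study.categories):
        if i == ref:
            continue
        if study.design == "case_control":
            out.append(math.log((a[i] * (n[ref] - a[ref])) / (a[ref] * (n[i] - a[i]))))
        else:
            out.append(math.log((a[i] / n[i]) / (a[ref] / n[ref])))
    return out


def test_log_rr_vector_hand_arithmetic():
    study = make_study(
        [
            make_category("ref", 0, 10, 6, 1.0, 1.0, 1.0, 20, 200, True),
            make_category("top", 10, 20, 15, 2.0, 1.0, 4.0, 30, 100),
        ]
    )
    lrr = log_rr_vector(study, 0.95)
    assert lrr.L == pytest.approx([math.log(2.0)], abs=1e-9)
    assert lrr.V == pytest.approx([0.1251], abs=2e-4)
    assert lrr.indices == (1,)  # reference excluded


def test_log_rr_vector_symmetric_halfwidths():
    # CI symmetric on the log scale: V from upper and lower half-width agree
    rr, f = 1.8, 1.45
    study = make_study(
        [
            make_category("ref", 0, 10, 6, 1.0, 1.0, 1.0, 20, 200, True),
            make_category("top", 10, 20, 15, rr, rr / f, rr * f, 30, 100),
        ]
    )
    (v,) = log_rr_vector(study).V
    z = 1.959963984540054
    assert v == pytest.approx((math.log(f) / z) ** 2, rel=1e-9)


def test_invalid_ci_raises():
    study = make_study(
        [
            make_category("ref", 0, 10, 6, 1.0, 1.0, 1.0, 20, 200, True),
            make_category("top", 10, 20, 15, 2.0, 3.0, 1.5, 30, 100),
        ]
    )
    with pytest.raises(InvalidCIError):
        log_rr_vector(study)


def test_two_category_closed_form():
    # totals (100, 100), 30 cases, RR 2 -> a = (10, 20)
    study = make_study(
        [
            make_category("ref", 0, 10, 5, 1.0, 1.0, 1.0, 12, 100, True),
            make_category("top", 10, 20, 15, 2.0, 1.0, 4.0, 18, 100),
        ]
    )
    lrr = LogRRVector(L=np.array([math.log(2.0)]), V=np.array([0.1]), indices=(1,))
    t = fit_pseudo_counts(study, lrr)
    assert t.a == pytest.approx([10.0, 20.0], abs=1e-8)


def test_null_association_splits_by_totals():
    # all L = 0 -> a_i = A * n_i / sum(n)
    study = make_study(
        [
            make_category("ref", 0, 10, 5, 1.0, 1.0, 1.0, 30, 300, True),
            make_category("mid", 10, 20, 15, 1.0, 0.8, 1.25, 10, 100),
            make_category("top", 20, 30, 25, 1.0, 0.8, 1.25, 20, 200),
        ]
    )
    lrr = log_rr_vector(study)
    t = fit_pseudo_counts(study, lrr)
    A, N = 60, 600
    assert t.a == pytest.approx([A * 300 / N, A * 100 / N, A * 200 / N], abs=1e-7)


def test_three_category_derived_solution(three_cat_study):
    """Totals (200,100,100), 60 cases, RRs (1.5, 2.0): the margin equation
    gives a_0 = 60/2.75; fitted crude RRs must reproduce the inputs."""
    L = np.array([math.log(1.5), math.log(2.0)])
    lrr = LogRRVector(L=L, V=np.array([0.05, 0.06]), indices=(1, 2))
    t = fit_pseudo_counts(three_cat_study, lrr)
    assert t.a == pytest.approx([21.818181818, 16.363636364, 21.818181818], abs=1e-6)
    assert crude_log_rr(three_cat_study, t.a) == pytest.approx(list(L), abs=1e-8)
    # margin conservation
    assert t.a.sum() == pytest.approx(60.0, abs=1e-8)


def test_covariance_off_diagonal_hand_value(three_cat_study):
    L = np.array([math.log(1.5), math.log(2.0)])
    lrr = LogRRVector(L=L, V=np.array([0.05, 0.06]), indices=(1, 2))
    t = fit_pseudo_counts(three_cat_study, lrr)
    full = covariance_matrix(t, lrr)
    # 1/a0 - 1/n0 = 1/21.8181... - 1/200
    assert full.C[0, 1] == pytest.approx(0.0408333, abs=1e-5)
    assert full.C[1, 0] == full.C[0, 1]
    assert np.diag(full.C) == pytest.approx([0.05, 0.06])  # reported variances kept
    np.linalg.cholesky(full.C)  # positive definite


def test_two_category_covariance_is_reported_variance():
    study = make_study(
        [
            make_category("ref", 0, 10, 5, 1.0, 1.0, 1.0, 12, 100, True),
            make_category("top", 10, 20, 15, 2.0, 1.0, 4.0, 18, 100),
        ]
    )
    lrr = log_rr_vector(study)
    full = covariance_matrix(fit_pseudo_counts(study, lrr), lrr)
    assert full.C.shape == (1, 1)
    assert full.C[0, 0] == pytest.approx(lrr.V[0])


@pytest.mark.parametrize("design", ["cumulative_incidence", "incidence_rate", "case_control"])
def test_grid_search_oracle_agreement(design):
    """Bisection agrees with a brute-force grid scan of the reference cell
    for every design's crude-RR formula."""
    study = make_study(
        [
            make_category("ref", 0, 10, 5, 1.0, 1.0, 1.0, 25, 250, True),
            make_category("mid", 10, 20, 15, 1.4, 1.0, 2.0, 20, 150),
            make_category("top", 20, 30, 25, 2.2, 1.4, 3.5, 30, 120),
        ],
        design=design,
    )
    lrr = log_rr_vector(study)
    t = fit_pseudo_counts(study, lrr)
    a0_grid = grid_search_a0(study, lrr.L)
    assert t.a0 == pytest.approx(a0_grid, abs=1e-3)
    assert crude_log_rr(study, t.a) == pytest.approx(list(lrr.L), abs=1e-8)
    assert t.a.sum() == pytest.approx(sum(c.cases for c in study.categories), rel=1e-8)


def test_incidence_rate_large_reference_gives_near_diagonal():
    study = make_study(
        [
            make_category("ref", 0, 10, 5, 1.0, 1.0, 1.0, 10**6, 10**7, True),
            make_category("mid", 10, 20, 15, 1.5, 1.2, 1.9, 100, 1000),
            make_category("top", 20, 30, 25, 2.0, 1.5, 2.7, 120, 900),
        ],
        design="incidence_rate",
    )
    lrr = log_rr_vector(study)
    full = covariance_matrix(fit_pseudo_counts(study, lrr), lrr)
    assert abs(full.C[0, 1]) < 1e-5  # 1/a0 -> 0


def test_monotone_sensitivity_of_reference_cell(rng):
    """Raising every log-RR pulls fitted cases out of the reference cell."""
    for _ in range(20):
        n = rng.integers(80, 300, size=3)
        cases = rng.integers(5, 40, size=3)
        study = make_study(
            [
                make_category("ref", 0, 10, 5, 1.0, 1.0, 1.0, int(cases[0]), int(n[0]), True),
                make_category("mid", 10, 20, 15, 1.3, 1.0, 1.8, int(cases[1]), int(n[1])),
                make_category("top", 20, 30, 25, 1.9, 1.3, 2.9, int(cases[2]), int(n[2])),
            ]
        )
        base = log_rr_vector(study)
        hi = LogRRVector(L=base.L + 0.3, V=base.V, indices=base.indices)
        a0_base = fit_pseudo_counts(study, base).a0
        a0_hi = fit_pseudo_counts(study, hi).a0
        assert a0_hi < a0_base


def test_zero_case_category_gets_continuity_correction(caplog):
    study = make_study(
        [
            make_category("ref", 0, 10, 5, 1.0, 1.0, 1.0, 10, 100, True),
            make_category("mid", 10, 20, 15, 1.5, 1.0, 2.3, 0, 100),
            make_category("top", 20, 30, 25, 2.0, 1.2, 3.3, 20, 100),
        ]
    )
    lrr = log_rr_vector(study)
    with caplog.at_level("WARNING", logger="drmeta"):
        t = fit_pseudo_counts(study, lrr)
    assert "continuity" in caplog.text
    assert t.a.sum() == pytest.approx(30.5, abs=1e-7)


def test_missing_counts_fall_back_to_diagonal(caplog):
    study = make_study(
        [
            make_category("ref", 0, 10, 5, 1.0, 1.0, 1.0, 0, 100, True),
            make_category("mid", 10, 20, 15, 1.5, 1.0, 2.3, 0, 100),
            make_category("top", 20, 30, 25, 2.0, 1.2, 3.3, 0, 100),
        ]
    )
    with caplog.at_level("WARNING", logger="drmeta"):
        lrr = study_covariance(study)
    assert "DIAGONAL" in caplog.text
    assert np.count_nonzero(lrr.C - np.diag(np.diag(lrr.C))) == 0
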