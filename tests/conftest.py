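import numpy as np
import pytest

from drmeta.study_io import CategoryRecord, StudyRecord
from drmeta.synthetic_data import SimSpec, TrueCurve, generate_meta_dataset


def make_category(
    label="c",
    dose_low=None,
    dose_high=None,
    dose_assigned=None,
    rr=1.5,
    ci_low=1.1,
    ci_high=2.1,
    cases=30,
    total=100,
    is_reference=False,
):
    return CategoryRecord(
        label=label,
        dose_low=dose_low,
        dose_high=dose_high,
        dose_assigned=dose_assigned,
        rr=rr,
        ci_low=ci_low,
        ci_high=ci_high,
        cases=cases,
        total=total,
        is_reference=is_reference,
    )


def make_study(
    categories,
    study_id="study_a",
    stratum_id="all",
    design="cumulative_incidence",
):
    return StudyRecord(
        study_id=study_id,
        stratum_id=stratum_id,
        design=design,
        categories=tuple(categories),
    )


@pytest.fixture
def three_cat_study():
    """Cumulative-incidence study matching a hand-solvable pseudo-count
    system: totals (200, 100, 100), 60 total cases, RRs (1, 1.5, 2)."""
    return make_study(
        [
            make_category("ref", 0, 10, 6.0, 1.0, 1.0, 1.0, 20, 200, True),
            make_category("mid", 10, 20, 15.0, 1.5, 1.0, 2.25, 18, 100),
            make_category("top", 20, 30, 25.0, 2.0, 1.2, 3.3333, 22, 100),
        ]
    )


@pytest.fixture
def synthetic_meta():
    """Five-cohort synthetic dataset under the default (linear, homogeneous)
    truth; reproducible."""
    spec = SimSpec(seed=42)
    return generate_meta_dataset(spec, TrueCurve())


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
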