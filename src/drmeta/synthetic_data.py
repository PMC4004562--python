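"""Synthetic category-level cohort studies with a known dose-response truth.

The published category-level tables behind this literature's pooled
estimates are scattered across primary sources, so end-to-end testing uses
simulated cohorts instead: participants are spread over ALT exposure
categories, events are drawn binomially with risk
``baseline · exp(logRR(dose))``, and each study is summarized exactly the
way sources report — crude category RRs with log-scale Wald CIs against
the lowest (reference) category.

Defaults emulate the five-cohort setting this package targets: participant
counts (3,545; 1,097; 21,535; 2,957; 681 — the published cohorts'
sizes), five categories from quintiles of a lognormal ALT
distribution (median 14 U/L, ln-sd 0.55, so category medians span roughly
6–40 U/L), per-study baseline risks calibrated so expected event counts
match the published per-cohort cases (309; 226; 802; 608; 180 — cohort
incidences range from 4% to 26%), and no between-study slope
heterogeneity.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study_io import CategoryRecord, StudyRecord

# Participant/case counts of the five published cohorts (largest table's
# margins: 29,815 participants, 2,125 incident events).
COHORT_SIZES = (3545, 1097, 21535, 2957, 681)
COHORT_CASES = (309, 226, 802, 608, 180)


@dataclass(frozen=True)
class TrueCurve:
    """Known dose-risk relationship on the log-RR per U/L scale.

    ``form``: "linear" (slope only), "spline" (slope changes by
    ``bend_slope`` beyond ``bend_dose``, smoothly via a quadratic ramp is
    unnecessary — a piecewise-linear bend suffices to violate linearity),
    or "threshold" (flat below ``bend_dose``, linear above).
    """

    form: str = "linear"
    slope: float = math.log(1.14) / 5.0
    baseline_risk: float = 0.05
    bend_dose: float = 20.0
    bend_slope: float = 0.0

    def log_rr(self, dose, reference_dose: float):
        d = np.asarray(dose, dtype=float)
        if self.form == "linear":
            return self.slope * (d - reference_dose)
        if self.form == "spline":
            base = self.slope * (d - reference_dose)
            kink = self.bend_slope * (
                np.clip(d - self.bend_dose, 0.0, None)
                - np.clip(reference_dose - self.bend_dose, 0.0, None)
            )
            return base + kink
        if self.form == "threshold":
            eff = np.clip(d, self.bend_dose, None)
            ref = max(reference_dose, self.bend_dose)
            return self.slope * (eff - ref)
        raise ValueError(f"unknown curve form {self.form!r}")


@dataclass(frozen=True)
class SimSpec:
    """Simulation design: study sizes, category structure, heterogeneity."""

    n_studies: int = 5
    participants: tuple[int, ...] = COHORT_SIZES
    cases: tuple[int, ...] | None = COHORT_CASES  # expected events per study
    n_categories: int = 5
    alt_log_median: float = math.log(14.0)
    alt_log_sd: float = 0.55
    tau2: float = 0.0  # between-study variance of the slope (per U/L scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.participants) != self.n_studies:
            raise ValueError("participants must list one count per study")
        if self.cases is not None and len(self.cases) != self.n_studies:
            raise ValueError("cases must list one expected count per study")
        if any(n <= 0 for n in self.participants):
            raise ValueError("participant counts must be positive")
        if not 3 <= self.n_categories <= 5:
            raise ValueError("n_categories must be between 3 and 5")
        if self.tau2 < 0:
            raise ValueError("tau2 must be nonnegative")


def _wald_ci(a_i, n_i, a_0, n_0, z: float = 1.959963984540054):
    """Crude log-RR Wald CI for a 2xK cumulative-incidence table.

    0.5 continuity correction applied to any zero cell.
    """
    if a_i == 0 or a_0 == 0:
        a_i, a_0 = a_i + 0.5, a_0 + 0.5
    rr = (a_i / n_i) / (a_0 / n_0)
    se = math.sqrt(1.0 / a_i - 1.0 / n_i + 1.0 / a_0 - 1.0 / n_0)
    return rr, rr * math.exp(-z * se), rr * math.exp(z * se)


def generate_study(
    spec: SimSpec,
    curve: TrueCurve,
    rng: np.random.Generator,
    n_participants: int | None = None,
    study_id: str = "synthetic",
    slope_shift: float = 0.0,
    target_cases: int | None = None,
) -> StudyRecord:
    """Simulate one cohort and summarize it in source-reporting format.

    Individual ALT values are drawn lognormal and cut at equal-probability
    quantiles into ``n_categories`` categories; the category dose is the
    within-category median.  Events are binomial at the category dose's
    risk.  When ``target_cases`` is given, the study's baseline risk is
    calibrated so the *expected* total event count equals it (the published
    cohorts' incidences vary widely, 4%–26%, so a shared baseline would
    misrepresent the small high-incidence cohorts); otherwise
    ``curve.baseline_risk`` applies.  ``slope_shift`` perturbs the linear
    component (used for between-study heterogeneity).  Raises
    ``ValueError`` before sampling if any category risk would reach 1.
    """
    n = int(n_participants if n_participants is not None else spec.participants[0])
    alt = rng.lognormal(spec.alt_log_median, spec.alt_log_sd, size=n)
    qs = np.quantile(alt, np.linspace(0, 1, spec.n_categories + 1))
    qs[0], qs[-1] = 0.0, np.inf
    idx = np.clip(np.searchsorted(qs, alt, side="right") - 1, 0, spec.n_categories - 1)

    doses, totals = [], []
    for c in range(spec.n_categories):
        sel = alt[idx == c]
        doses.append(float(np.median(sel)))
        totals.append(int(sel.size))
    ref_dose = doses[0]

    log_rr = np.asarray(curve.log_rr(np.array(doses), ref_dose), dtype=float)
    log_rr = log_rr + slope_shift * (np.array(doses) - ref_dose)
    if target_cases is not None:
        baseline = target_cases / float(np.sum(np.array(totals) * np.exp(log_rr)))
    else:
        baseline = curve.baseline_risk
    risks = baseline * np.exp(log_rr)
    if np.any(risks >= 1.0):
        raise ValueError(
            f"risk reaches {risks.max():.3f} >= 1 at dose "
            f"{doses[int(np.argmax(risks))]:.1f}; lower baseline_risk or slope"
        )
    cases = rng.binomial(totals, risks)

    cats = []
    for c in range(spec.n_categories):
        if c == 0:
            rr, lo, hi = 1.0, 1.0, 1.0
        else:
            rr, lo, hi = _wald_ci(int(cases[c]), totals[c], int(cases[0]), totals[0])
        bounds_lo = None if c == 0 else float(qs[c])
        bounds_hi = None if c == spec.n_categories - 1 else float(qs[c + 1])
        cats.append(
            CategoryRecord(
                label=f"Q{c + 1}",
                dose_low=bounds_lo,
                dose_high=bounds_hi,
                dose_assigned=doses[c],
                rr=rr,
                ci_low=lo,
                ci_high=hi,
                cases=int(cases[c]),
                total=totals[c],
                is_reference=(c == 0),
            )
        )
    return StudyRecord(
        study_id=study_id,
        stratum_id="all",
        design="cumulative_incidence",
        categories=tuple(cats),
        followup_years=5.0,
    )


def generate_meta_dataset(
    spec: SimSpec, curve: TrueCurve, rng: np.random.Generator | None = None
) -> list[StudyRecord]:
    """Simulate ``spec.n_studies`` cohorts with study-specific slopes drawn
    from ``Normal(true slope, τ²)``; reproducible from ``spec.seed`` when no
    generator is passed."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    shifts = (
        rng.normal(0.0, math.sqrt(spec.tau2), size=spec.n_studies)
        if spec.tau2 > 0
        else np.zeros(spec.n_studies)
    )
    return [
        generate_study(
            spec,
            curve,
            rng,
            n_participants=spec.participants[i],
            study_id=f"study_{i + 1:02d}",
            slope_shift=float(shifts[i]),
            target_cases=None if spec.cases is None else spec.cases[i],
        )
        for i in range(spec.n_studies)
    ]


def cohort_characteristics() -> list[StudyRecord]:
    """The five published cohorts' study-level characteristics.

    Metadata only — the primary sources' category-level RR tables are not
    part of the fixture, so each record carries a single placeholder
    category holding the study's participant and event totals.  The records
    serve bookkeeping and sizing purposes (totals 29,815 participants,
    2,125 events); they are not fit for trend estimation.
    """
    path = importlib.resources.files("drmeta.data") / "cohort_characteristics.csv"
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            StudyRecord(
                study_id=str(row["study_id"]),
                stratum_id="all",
                design=str(row["design"]),
                categories=(
                    CategoryRecord(
                        label="all participants",
                        dose_low=None,
                        dose_high=None,
                        dose_assigned=None,
                        rr=1.0,
                        ci_low=1.0,
                        ci_high=1.0,
                        cases=float(row["cases"]),
                        total=float(row["total"]),
                        is_reference=True,
                    ),
                ),
                followup_years=float(row["followup_years"]),
                covariates_note=f"location: {row['location']}",
            )
        )
    return out
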