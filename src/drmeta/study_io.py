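"""Study-level data model and delimited-table input/output.

A *study table* is a long-format CSV: one row per exposure category, keyed
by (study_id, stratum_id).  Each study (or sex/subgroup stratum) reports an
adjusted relative risk with a 95% CI for every alanine-aminotransferase
(ALT) category relative to an explicitly flagged reference category, plus
the event count and the number of participants (or amount of person-time)
in each category.  These are the raw materials for generalized
least-squares dose-response trend estimation.

Expected CSV columns (UTF-8, comma-separated, header row)::

    study_id, stratum_id, design, label, dose_low, dose_high,
    dose_assigned, rr, ci_low, ci_high, cases, total, is_reference,
    followup_years

Empty strings encode absent optional values (open interval bounds,
unreported category medians).  ``design`` is one of ``cumulative_incidence``,
``incidence_rate`` or ``case_control``.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

DESIGNS = ("cumulative_incidence", "incidence_rate", "case_control")

REQUIRED_COLUMNS = (
    "study_id",
    "stratum_id",
    "design",
    "label",
    "dose_low",
    "dose_high",
    "dose_assigned",
    "rr",
    "ci_low",
    "ci_high",
    "cases",
    "total",
    "is_reference",
)

OPTIONAL_COLUMNS = ("followup_years", "covariates_note")


class SchemaError(ValueError):
    """The table header does not match the documented schema."""


class RowParseError(ValueError):
    """A cell could not be parsed; carries the 1-based data line number."""

    def __init__(self, line: int, column: str, value: object):
        self.line = line
        self.column = column
        super().__init__(
            f"line {line}: cannot parse column {column!r} from value {value!r}"
        )


@dataclass(frozen=True)
class CategoryRecord:
    """One exposure category of one study.

    Doses are ALT levels in U/L.  ``dose_low``/``dose_high`` are the
    category interval bounds (``None`` for an open bound), ``dose_assigned``
    the reported category median or midpoint when the source printed one.
    ``rr`` is the adjusted relative risk versus the reference category with
    95% CI (``ci_low``, ``ci_high``); the reference category carries
    ``rr = 1`` with a degenerate CI.  ``total`` is a participant count for
    cumulative-incidence and case-control designs, person-time for
    incidence-rate designs.
    """

    label: str
    dose_low: float | None
    dose_high: float | None
    dose_assigned: float | None
    rr: float
    ci_low: float
    ci_high: float
    cases: float
    total: float
    is_reference: bool = False


@dataclass(frozen=True)
class StudyRecord:
    """A study or within-study stratum with its ordered exposure categories."""

    study_id: str
    stratum_id: str
    design: str
    categories: tuple[CategoryRecord, ...]
    followup_years: float | None = None
    covariates_note: str = ""

    @property
    def reference_index(self) -> int:
        for i, c in enumerate(self.categories):
            if c.is_reference:
                return i
        raise ValueError(f"study {self.study_id}: no reference category")

    @property
    def n_categories(self) -> int:
        return len(self.categories)


@dataclass
class RunConfig:
    """Effective run configuration with the pipeline defaults.

    ``increment`` is the dose step (U/L) used to report the trend as a
    relative risk; ``knot_percentiles`` place the three restricted-cubic-
    spline knots on the pooled, total-weighted category-dose distribution;
    ``reference_dose`` anchors the predicted curve at RR = 1 (``None`` means
    the lowest assigned dose in the data).
    """

    increment: float = 5.0
    ci_level: float = 0.95
    knot_percentiles: tuple[float, float, float] = (0.25, 0.50, 0.75)
    pooling_model: str = "random"
    reference_dose: float | None = None
    seed: int = 0
    tol: float = 1e-10
    max_iter: int = 200
    dose_strategy: str = "median_then_midpoint"
    open_interval: str = "half_adjacent_width"
    curve_points: int = 100

    def __post_init__(self) -> None:
        ks = tuple(float(k) for k in self.knot_percentiles)
        if len(ks) != 3 or not all(0.0 < k < 1.0 for k in ks):
            raise ValueError("knot_percentiles must be three fractions in (0, 1)")
        if not (ks[0] < ks[1] < ks[2]):
            raise ValueError("knot_percentiles must be strictly increasing")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.pooling_model not in ("fixed", "random"):
            raise ValueError("pooling_model must be 'fixed' or 'random'")
        self.knot_percentiles = ks

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["knot_percentiles"] = list(self.knot_percentiles)
        return d


@dataclass(frozen=True)
class ValidationFinding:
    """A single violated rule, attributed to a study/field."""

    study_id: str
    stratum_id: str
    field: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"[{self.study_id}/{self.stratum_id}] {self.field}: "
            f"{self.rule} — {self.message}"
        )


def _parse_float(value, line: int, column: str, required: bool) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        if required:
            raise RowParseError(line, column, value)
        return None
    s = str(value).strip()
    if s == "":
        if required:
            raise RowParseError(line, column, value)
        return None
    try:
        return float(s.replace(",", ""))
    except ValueError as exc:
        raise RowParseError(line, column, s) from exc


def _parse_bool(value, line: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n", ""):
        return False
    raise RowParseError(line, column, value)


def _category_sort_key(c: CategoryRecord) -> float:
    if c.dose_assigned is not None:
        return c.dose_assigned
    if c.dose_low is not None and c.dose_high is not None:
        return 0.5 * (c.dose_low + c.dose_high)
    if c.dose_low is not None:
        return c.dose_low
    if c.dose_high is not None:
        return c.dose_high
    return math.inf


def read_study_table(path: str | os.PathLike) -> list[StudyRecord]:
    """Read a long-format study table into validated, ordered records.

    One :class:`StudyRecord` is produced per (study_id, stratum_id) pair, in
    first-appearance order; categories are sorted by increasing dose.
    Raises :class:`SchemaError` for a missing column and
    :class:`RowParseError` (with the data line number) for an unparseable
    cell.  Validation findings are *not* raised here — run
    :func:`validate_study` on the result.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    groups: dict[tuple[str, str], list[CategoryRecord]] = {}
    meta: dict[tuple[str, str], dict] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        key = (str(row["study_id"]).strip(), str(row["stratum_id"]).strip() or "all")
        cat = CategoryRecord(
            label=str(row["label"]).strip(),
            dose_low=_parse_float(row["dose_low"], line, "dose_low", False),
            dose_high=_parse_float(row["dose_high"], line, "dose_high", False),
            dose_assigned=_parse_float(
                row["dose_assigned"], line, "dose_assigned", False
            ),
            rr=_parse_float(row["rr"], line, "rr", True),
            ci_low=_parse_float(row["ci_low"], line, "ci_low", True),
            ci_high=_parse_float(row["ci_high"], line, "ci_high", True),
            cases=_parse_float(row["cases"], line, "cases", True),
            total=_parse_float(row["total"], line, "total", True),
            is_reference=_parse_bool(row["is_reference"], line, "is_reference"),
        )
        if key not in groups:
            groups[key] = []
            fy = None
            if "followup_years" in df.columns:
                fy = _parse_float(row["followup_years"], line, "followup_years", False)
            meta[key] = {
                "design": str(row["design"]).strip(),
                "followup_years": fy,
                "covariates_note": str(row.get("covariates_note", "") or "").strip()
                if "covariates_note" in df.columns
                else "",
            }
        groups[key].append(cat)

    records = []
    for key, cats in groups.items():
        cats_sorted = tuple(sorted(cats, key=_category_sort_key))
        records.append(
            StudyRecord(
                study_id=key[0],
                stratum_id=key[1],
                design=meta[key]["design"],
                categories=cats_sorted,
                followup_years=meta[key]["followup_years"],
                covariates_note=meta[key]["covariates_note"],
            )
        )
    return records


def validate_study(record: StudyRecord) -> list[ValidationFinding]:
    """Check every data-model invariant; findings are data, never exceptions.

    An empty list means the record is fit for trend estimation: at least 3
    categories, exactly one reference with RR = 1, positive RRs bracketed by
    their CIs, cases not exceeding participant totals for cumulative-
    incidence designs, and coherent interval bounds.
    """
    f: list[ValidationFinding] = []

    def add(field_name: str, rule: str, message: str) -> None:
        f.append(
            ValidationFinding(record.study_id, record.stratum_id, field_name, rule, message)
        )

    if record.design not in DESIGNS:
        add("design", "unknown-design", f"design {record.design!r} not one of {DESIGNS}")
    if len(record.categories) < 3:
        add(
            "categories",
            "fewer than 3 categories",
            f"{len(record.categories)} categories; at least 3 are required for "
            "trend estimation",
        )
    n_ref = sum(c.is_reference for c in record.categories)
    if n_ref != 1:
        add(
            "is_reference",
            "reference-count",
            f"expected exactly one reference category, found {n_ref}",
        )
    for c in record.categories:
        where = f"category {c.label!r}"
        if c.is_reference:
            if not math.isclose(c.rr, 1.0, rel_tol=1e-9):
                add("rr", "reference-rr", f"{where}: reference RR must be 1, got {c.rr}")
        else:
            if not (c.rr > 0 and c.ci_low > 0 and c.ci_high > 0):
                add("rr", "positive-rr", f"{where}: rr and CI bounds must be > 0")
            elif not (c.ci_low <= c.rr <= c.ci_high):
                add(
                    "ci",
                    "ci-brackets-rr",
                    f"{where}: CI ({c.ci_low}, {c.ci_high}) does not bracket rr {c.rr}",
                )
        if c.cases < 0:
            add("cases", "nonnegative-cases", f"{where}: cases {c.cases} < 0")
        if not c.total > 0:
            add("total", "positive-total", f"{where}: total {c.total} must be > 0")
        if record.design == "cumulative_incidence":
            if c.cases > c.total:
                add("cases", "cases exceed total", f"{where}: {c.cases} > {c.total}")
            if c.total == c.total and abs(c.total - round(c.total)) > 1e-9:
                add(
                    "total",
                    "integer-total",
                    f"{where}: participant totals must be integers for "
                    "cumulative-incidence designs",
                )
        if c.dose_low is not None and c.dose_high is not None and not (
            c.dose_low < c.dose_high
        ):
            add(
                "dose_low",
                "interval-order",
                f"{where}: dose_low {c.dose_low} not below dose_high {c.dose_high}",
            )
    assigned = [c.dose_assigned for c in record.categories]
    if all(a is not None for a in assigned) and len(assigned) > 1:
        if any(b <= a for a, b in zip(assigned, assigned[1:])):
            add(
                "dose_assigned",
                "monotone-doses",
                f"assigned doses {assigned} not strictly increasing",
            )
    return f


def validate_all(records: Iterable[StudyRecord]) -> list[ValidationFinding]:
    out: list[ValidationFinding] = []
    for r in records:
        out.extend(validate_study(r))
    return out


def studies_to_frame(records: Sequence[StudyRecord]) -> pd.DataFrame:
    """Flatten records back to the long CSV schema (inverse of reading)."""
    rows = []
    for r in records:
        for c in r.categories:
            rows.append(
                {
                    "study_id": r.study_id,
                    "stratum_id": r.stratum_id,
                    "design": r.design,
                    "label": c.label,
                    "dose_low": c.dose_low,
                    "dose_high": c.dose_high,
                    "dose_assigned": c.dose_assigned,
                    "rr": c.rr,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "cases": c.cases,
                    "total": c.total,
                    "is_reference": int(c.is_reference),
                    "followup_years": r.followup_years,
                }
            )
    return pd.DataFrame(rows)


def write_study_table(records: Sequence[StudyRecord], path: str | os.PathLike) -> None:
    studies_to_frame(records).to_csv(path, index=False)


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_results(summary: dict, curve: pd.DataFrame, per_study: pd.DataFrame, out_dir: str | os.PathLike) -> dict:
    """Write the pooled summary (JSON), curve table and per-study trend table.

    Returns a manifest dict mapping artifact names to file paths.  Output is
    deterministic: keys sorted, fixed float formatting, no timestamps.
    """
    os.makedirs(out_dir, exist_ok=True)
    summary_path = os.path.join(out_dir, "summary.json")
    curve_path = os.path.join(out_dir, "curve.tsv")
    per_study_path = os.path.join(out_dir, "per_study.tsv")
    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    curve.to_csv(curve_path, sep="\t", index=False, float_format="%.12g")
    per_study.to_csv(per_study_path, sep="\t", index=False, float_format="%.12g")
    return {
        "summary": summary_path,
        "curve": curve_path,
        "per_study": per_study_path,
    }
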