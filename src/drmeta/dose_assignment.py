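"""Assign a scalar dose to every exposure category.

Sources report ALT categories as intervals, often open-ended at the top
(e.g. "≥ 40 U/L") or bottom ("< 10 U/L"), sometimes with the in-category
median.  Trend estimation needs one number per category.  Rules, in order:

1. a reported median (``dose_assigned``) is used verbatim;
2. a closed interval gets its midpoint;
3. an open interval gets the closed bound shifted by half the width of the
   adjacent closed category (a standard convention in dose-response
   meta-analysis; the bottom-open case is floored at 0 U/L since ALT
   cannot be negative).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .study_io import CategoryRecord, StudyRecord


class UnassignableDoseError(ValueError):
    """Category has no assigned dose, no bounds, and no usable neighbor."""


class DoseOrderingError(ValueError):
    """Assigned doses are not strictly increasing across categories."""


@dataclass(frozen=True)
class DoseRule:
    """Strategy knobs for dose assignment (see module docstring)."""

    strategy: str = "median_then_midpoint"
    open_interval: str = "half_adjacent_width"
    floor: float = 0.0


def assign_dose(
    category: CategoryRecord,
    neighbor_widths: tuple[float | None, float | None] = (None, None),
    rule: DoseRule = DoseRule(),
) -> float:
    """Return the scalar dose for one category.

    ``neighbor_widths`` holds the widths of the closed categories adjacent
    below and above (either may be ``None``); only open intervals use them.
    Idempotent: a category with ``dose_assigned`` set returns it unchanged.
    """
    if category.dose_assigned is not None:
        return float(category.dose_assigned)
    lo, hi = category.dose_low, category.dose_high
    if lo is not None and hi is not None:
        return 0.5 * (lo + hi)
    below, above = neighbor_widths
    if lo is not None and hi is None:
        # open-top: lower bound + half the adjacent closed width
        if below is None:
            raise UnassignableDoseError(
                f"category {category.label!r}: open-top interval with no "
                "adjacent closed category"
            )
        return lo + 0.5 * below
    if hi is not None and lo is None:
        # open-bottom: upper bound - half the adjacent closed width
        if above is None:
            raise UnassignableDoseError(
                f"category {category.label!r}: open-bottom interval with no "
                "adjacent closed category"
            )
        return max(rule.floor, hi - 0.5 * above)
    raise UnassignableDoseError(
        f"category {category.label!r}: no dose_assigned and no interval bounds"
    )


def _closed_width(c: CategoryRecord) -> float | None:
    if c.dose_low is not None and c.dose_high is not None:
        return c.dose_high - c.dose_low
    return None


def assign_all(study: StudyRecord, rule: DoseRule = DoseRule()) -> StudyRecord:
    """Return a copy of ``study`` with every category's dose_assigned set.

    Neighbor widths come from the nearest *closed* category on the relevant
    side.  Raises :class:`DoseOrderingError` naming the offending categories
    if the resulting doses are not strictly increasing.
    """
    cats = list(study.categories)
    k = len(cats)
    widths = [_closed_width(c) for c in cats]

    def nearest_closed(idx: int, direction: int) -> float | None:
        j = idx + direction
        while 0 <= j < k:
            if widths[j] is not None:
                return widths[j]
            j += direction
        return None

    new_cats = []
    for i, c in enumerate(cats):
        d = assign_dose(c, (nearest_closed(i, -1), nearest_closed(i, +1)), rule)
        new_cats.append(dataclasses.replace(c, dose_assigned=d))

    doses = [c.dose_assigned for c in new_cats]
    for i in range(1, k):
        if doses[i] <= doses[i - 1]:
            raise DoseOrderingError(
                f"study {study.study_id}/{study.stratum_id}: assigned doses not "
                f"strictly increasing between categories "
                f"{new_cats[i - 1].label!r} ({doses[i - 1]}) and "
                f"{new_cats[i].label!r} ({doses[i]})"
            )
    return dataclasses.replace(study, categories=tuple(new_cats))
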