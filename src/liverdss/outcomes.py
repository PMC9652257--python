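"""Single-outcome dichotomies and the three composite outcome measures.

Boundary semantics follow the clinical conventions throughout: the favorable
side is inclusive (operative time <= 240 min, blood loss <= 500 ml, stay
<= 5 days), so a value exactly on the threshold still counts as favorable.

Composites:

* operative outcome (OO) — no conversion, operative time <= 240 min and
  blood loss <= 500 ml;
* postoperative outcome (PO) — no complication of any grade and stay
  <= 5 days;
* textbook outcome (TO) — all-or-none: no moderate/severe intraoperative
  event (Satava > I), no severe complication (Clavien–Dindo > II), no
  prolonged stay (> 75th percentile of the series), R0 margin, and no
  90-day readmission or mortality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from .cohort import CohortTable, OutcomeRecord
from .errors import EmptyCohortError

__all__ = [
    "OutcomeFlags",
    "CompositeFlags",
    "outcome_flags",
    "operative_outcome",
    "postoperative_outcome",
    "los_percentile_threshold",
    "textbook_outcome",
    "composite_flags",
]


@dataclass(frozen=True)
class OutcomeFlags:
    """Dichotomized single outcomes (True = unfavorable side)."""

    long_operative_time: bool
    high_blood_loss: bool
    conversion: bool
    prolonged_los: bool
    any_complication: bool
    severe_complication: bool

    COLUMNS = (
        "long_operative_time",
        "high_blood_loss",
        "conversion",
        "prolonged_los",
        "any_complication",
        "severe_complication",
    )


@dataclass(frozen=True)
class CompositeFlags:
    """The three composite measures (True = achieved)."""

    oo: bool
    po: bool
    to: bool
    to_los_threshold_days: int

    COLUMNS = ("oo", "po", "to", "to_los_threshold_days")


def outcome_flags(rec: OutcomeRecord) -> OutcomeFlags:
    """Binarize the five single outcomes of one record."""
    return OutcomeFlags(
        long_operative_time=rec.operative_time_min > 240,
        high_blood_loss=rec.blood_loss_ml > 500,
        conversion=rec.conversion,
        prolonged_los=rec.los_days > 5,
        any_complication=rec.clavien_dindo >= 1,
        severe_complication=rec.clavien_dindo >= 3,
    )


def operative_outcome(rec: OutcomeRecord) -> bool:
    """No conversion, operative time <= 240 min, blood loss <= 500 ml."""
    return (
        not rec.conversion
        and rec.operative_time_min <= 240
        and rec.blood_loss_ml <= 500
    )


def postoperative_outcome(rec: OutcomeRecord) -> bool:
    """No complication of any grade and hospital stay <= 5 days."""
    return rec.clavien_dindo == 0 and rec.los_days <= 5


def los_percentile_threshold(cohort: CohortTable, q: float = 0.75) -> int:
    """Nearest-rank (type-1) percentile of length of stay over the cohort.

    Returns the smallest observed value whose cumulative proportion is >= q.
    Length of stay is integer-valued, so interpolating definitions disagree;
    the nearest-rank value is always an observed stay.
    """
    if len(cohort) == 0:
        raise EmptyCohortError("LOS percentile of an empty cohort is undefined")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    values = sorted(o.los_days for o in cohort.outcomes())
    k = math.ceil(q * len(values))
    return values[k - 1]


def textbook_outcome(rec: OutcomeRecord, los_threshold_days: int) -> bool:
    """All-or-none textbook outcome at the given prolonged-stay threshold."""
    if los_threshold_days < 1:
        raise ValueError("los_threshold_days must be >= 1")
    return (
        rec.satava_grade in ("none", "I")
        and rec.clavien_dindo <= 2
        and rec.los_days <= los_threshold_days
        and rec.margin == "R0"
        and not rec.readmission_90d
        and not rec.mortality_90d
    )


def composite_flags(rec: OutcomeRecord, los_threshold_days: int) -> CompositeFlags:
    """Evaluate all three composites for one record."""
    return CompositeFlags(
        oo=operative_outcome(rec),
        po=postoperative_outcome(rec),
        to=textbook_outcome(rec, los_threshold_days),
        to_los_threshold_days=los_threshold_days,
    )
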