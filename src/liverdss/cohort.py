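"""Typed cohort data model with CSV round-trip and Table-1-style summaries.

One patient is a (:class:`PatientRecord`, :class:`OutcomeRecord`) pair.  A
patient may have undergone several resections in the same procedure; each is
a :class:`ResectionTarget`.  On disk the cohort is a flat CSV with one row
per resection target; rows of the same patient share ``patient_id`` and are
ordered by ``resection_index``, with patient- and outcome-level fields
repeated on every row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .errors import CohortSchemaError, CohortValidationError, EmptyCohortError
from .segments import SEGMENTS, normalize_segments

__all__ = [
    "RESECTION_TYPES",
    "MAJOR_RESECTION_TYPES",
    "ResectionTarget",
    "PatientRecord",
    "OutcomeRecord",
    "CohortTable",
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
]

logger = logging.getLogger(__name__)

RESECTION_TYPES = (
    "wedge",
    "anatomical_segmentectomy",
    "left_lateral_sectionectomy",
    "sectionectomy_other",
    "left_hepatectomy",
    "right_hepatectomy",
    "central_hepatectomy",
    "extended_hepatectomy",
)

#: Resection types that are major hepatectomies by name (Brisbane).
MAJOR_RESECTION_TYPES = frozenset(
    {"left_hepatectomy", "right_hepatectomy", "central_hepatectomy", "extended_hepatectomy"}
)

SEXES = ("M", "F")
CHILD_PUGH = ("A", "B")
HISTOLOGIES = ("healthy", "steatosis", "cirrhosis")
APPROACHES = ("pure_laparoscopic", "hybrid_or_hand_assisted")
SATAVA_GRADES = ("none", "I", "II", "III")
MARGINS = ("R0", "R1")


@dataclass(frozen=True)
class ResectionTarget:
    """One resected territory: what was removed, where, and what for."""

    resection_type: str
    segments: frozenset[str]
    tumor_size_cm: float
    malignant: bool
    proximity_major_vessels: bool

    def __post_init__(self) -> None:
        if self.resection_type not in RESECTION_TYPES:
            raise ValueError(f"unknown resection_type: {self.resection_type!r}")
        object.__setattr__(self, "segments", normalize_segments(self.segments))
        if self.tumor_size_cm < 0:
            raise ValueError("tumor_size_cm must be >= 0")


@dataclass(frozen=True)
class PatientRecord:
    """Pre/intra-operative features feeding the four difficulty scores."""

    patient_id: str
    age_years: int
    sex: str
    bmi: float
    asa: int
    child_pugh: str
    platelets_1e9_per_L: float
    portal_hypertension: bool
    liver_histology: str
    previous_open_liver_resection: bool
    neoadjuvant_chemotherapy: bool
    comorb_cardiologic: bool
    comorb_vascular: bool
    comorb_diabetes: bool
    comorb_respiratory: bool
    comorb_neurologic: bool
    comorb_ckd: bool
    approach: str
    resections: tuple[ResectionTarget, ...]

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if self.bmi <= 0:
            raise ValueError("bmi must be > 0")
        if self.asa not in (1, 2, 3, 4):
            raise ValueError("asa must be in 1..4")
        if self.child_pugh not in CHILD_PUGH:
            raise ValueError("child_pugh must be A or B")
        if self.platelets_1e9_per_L <= 0:
            raise ValueError("platelets_1e9_per_L must be > 0")
        if self.liver_histology not in HISTOLOGIES:
            raise ValueError(f"liver_histology must be one of {HISTOLOGIES}")
        if self.approach not in APPROACHES:
            raise ValueError(f"approach must be one of {APPROACHES}")
        object.__setattr__(self, "resections", tuple(self.resections))
        if not self.resections:
            raise ValueError("resections list must be non-empty")


@dataclass(frozen=True)
class OutcomeRecord:
    """Peri-operative results for one patient."""

    operative_time_min: int
    blood_loss_ml: int
    conversion: bool
    transfusion: bool
    satava_grade: str
    clavien_dindo: int
    los_days: int
    margin: str
    readmission_90d: bool
    mortality_90d: bool

    def __post_init__(self) -> None:
        if self.operative_time_min <= 0:
            raise ValueError("operative_time_min must be > 0")
        if self.blood_loss_ml < 0:
            raise ValueError("blood_loss_ml must be >= 0")
        if self.satava_grade not in SATAVA_GRADES:
            raise ValueError(f"satava_grade must be one of {SATAVA_GRADES}")
        if not 0 <= self.clavien_dindo <= 5:
            raise ValueError("clavien_dindo must be in 0..5")
        if self.los_days < 1:
            raise ValueError("los_days must be >= 1")
        if self.margin not in MARGINS:
            raise ValueError("margin must be R0 or R1")
        if self.mortality_90d and self.clavien_dindo != 5:
            raise ValueError("mortality_90d requires clavien_dindo = 5")


@dataclass
class CohortTable:
    """An in-memory cohort: one (patient, outcome) pair per patient."""

    rows: list[tuple[PatientRecord, OutcomeRecord]]
    provenance: str = "observed"
    generator_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.provenance not in ("observed", "synthetic"):
            raise ValueError("provenance must be 'observed' or 'synthetic'")
        ids = [p.patient_id for p, _ in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("patient_id must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.rows)

    def patients(self) -> list[PatientRecord]:
        return [p for p, _ in self.rows]

    def outcomes(self) -> list[OutcomeRecord]:
        return [o for _, o in self.rows]


# ---------------------------------------------------------------------------
# CSV schema
# ---------------------------------------------------------------------------

_PATIENT_COLS = (
    "patient_id",
    "age_years",
    "sex",
    "bmi",
    "asa",
    "child_pugh",
    "platelets_1e9_per_L",
    "portal_hypertension",
    "liver_histology",
    "previous_open_liver_resection",
    "neoadjuvant_chemotherapy",
    "comorb_cardiologic",
    "comorb_vascular",
    "comorb_diabetes",
    "comorb_respiratory",
    "comorb_neurologic",
    "comorb_ckd",
    "approach",
)
_TARGET_COLS = (
    "resection_type",
    "segments",
    "tumor_size_cm",
    "malignant",
    "proximity_major_vessels",
)
_OUTCOME_COLS = (
    "operative_time_min",
    "blood_loss_ml",
    "conversion",
    "transfusion",
    "satava_grade",
    "clavien_dindo",
    "los_days",
    "margin",
    "readmission_90d",
    "mortality_90d",
)

COHORT_COLUMNS: tuple[str, ...] = (
    ("patient_id", "resection_index")
    + _PATIENT_COLS[1:]
    + _TARGET_COLS
    + _OUTCOME_COLS
)

_BOOL_PATIENT_FIELDS = {
    "portal_hypertension",
    "previous_open_liver_resection",
    "neoadjuvant_chemotherapy",
    "comorb_cardiologic",
    "comorb_vascular",
    "comorb_diabetes",
    "comorb_respiratory",
    "comorb_neurologic",
    "comorb_ckd",
}
_BOOL_OUTCOME_FIELDS = {"conversion", "transfusion", "readmission_90d", "mortality_90d"}


def _parse_bool(value: str, field: str) -> bool:
    if value == "1":
        return True
    if value == "0":
        return False
    raise ValueError(f"{field}: expected 0/1, got {value!r}")


def _parse_int(value: str, field: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValueError(f"{field}: expected integer, got {value!r}") from None


def _parse_float(value: str, field: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValueError(f"{field}: expected number, got {value!r}") from None


def _build_patient(first: dict, targets: Sequence[ResectionTarget]) -> PatientRecord:
    return PatientRecord(
        patient_id=first["patient_id"],
        age_years=_parse_int(first["age_years"], "age_years"),
        sex=first["sex"],
        bmi=_parse_float(first["bmi"], "bmi"),
        asa=_parse_int(first["asa"], "asa"),
        child_pugh=first["child_pugh"],
        platelets_1e9_per_L=_parse_float(first["platelets_1e9_per_L"], "platelets_1e9_per_L"),
        portal_hypertension=_parse_bool(first["portal_hypertension"], "portal_hypertension"),
        liver_histology=first["liver_histology"],
        previous_open_liver_resection=_parse_bool(
            first["previous_open_liver_resection"], "previous_open_liver_resection"
        ),
        neoadjuvant_chemotherapy=_parse_bool(
            first["neoadjuvant_chemotherapy"], "neoadjuvant_chemotherapy"
        ),
        comorb_cardiologic=_parse_bool(first["comorb_cardiologic"], "comorb_cardiologic"),
        comorb_vascular=_parse_bool(first["comorb_vascular"], "comorb_vascular"),
        comorb_diabetes=_parse_bool(first["comorb_diabetes"], "comorb_diabetes"),
        comorb_respiratory=_parse_bool(first["comorb_respiratory"], "comorb_respiratory"),
        comorb_neurologic=_parse_bool(first["comorb_neurologic"], "comorb_neurologic"),
        comorb_ckd=_parse_bool(first["comorb_ckd"], "comorb_ckd"),
        approach=first["approach"],
        resections=tuple(targets),
    )


def _build_target(row: dict, plain_segment4: str) -> ResectionTarget:
    labels = [s for s in str(row["segments"]).split(";") if s.strip()]
    return ResectionTarget(
        resection_type=row["resection_type"],
        segments=normalize_segments(labels, plain_segment4=plain_segment4),
        tumor_size_cm=_parse_float(row["tumor_size_cm"], "tumor_size_cm"),
        malignant=_parse_bool(row["malignant"], "malignant"),
        proximity_major_vessels=_parse_bool(
            row["proximity_major_vessels"], "proximity_major_vessels"
        ),
    )


def _build_outcome(first: dict) -> OutcomeRecord:
    return OutcomeRecord(
        operative_time_min=_parse_int(first["operative_time_min"], "operative_time_min"),
        blood_loss_ml=_parse_int(first["blood_loss_ml"], "blood_loss_ml"),
        conversion=_parse_bool(first["conversion"], "conversion"),
        transfusion=_parse_bool(first["transfusion"], "transfusion"),
        satava_grade=first["satava_grade"],
        clavien_dindo=_parse_int(first["clavien_dindo"], "clavien_dindo"),
        los_days=_parse_int(first["los_days"], "los_days"),
        margin=first["margin"],
        readmission_90d=_parse_bool(first["readmission_90d"], "readmission_90d"),
        mortality_90d=_parse_bool(first["mortality_90d"], "mortality_90d"),
    )


def read_cohort(path, strict: bool = True, plain_segment4: str = "4b") -> CohortTable:
    """Read a cohort CSV.

    In strict mode any invalid row aborts the read with a
    :class:`CohortValidationError` naming field and CSV line.  In non-strict
    mode offending patients are dropped and counted in the log — mirroring a
    registry analysis that excludes records with unusable score inputs.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise CohortSchemaError(f"cannot parse CSV {path}: {exc}") from exc

    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    rows: list[tuple[PatientRecord, OutcomeRecord]] = []
    errors: list[str] = []
    n_dropped = 0
    for pid, group in df.groupby("patient_id", sort=False):
        group = group.sort_values(
            "resection_index", key=lambda s: s.astype(int), kind="stable"
        )
        first = group.iloc[0].to_dict()
        lineno = int(group.index[0]) + 2  # 1-based + header
        try:
            targets = [
                _build_target(r.to_dict(), plain_segment4) for _, r in group.iterrows()
            ]
            patient = _build_patient(first, targets)
            outcome = _build_outcome(first)
        except ValueError as exc:
            msg = f"row {lineno} (patient {pid}): {exc}"
            if strict:
                errors.append(msg)
            else:
                n_dropped += 1
                logger.warning("dropping invalid patient: %s", msg)
            continue
        rows.append((patient, outcome))

    if errors:
        raise CohortValidationError(errors)
    if n_dropped:
        logger.info("read_cohort: dropped %d invalid patient(s)", n_dropped)
    return CohortTable(rows=rows, provenance="observed")


def _fmt_float(x: float) -> str:
    return repr(float(x))


def _segment_sort_key(label: str) -> int:
    return SEGMENTS.index(label)


def cohort_to_frame(cohort: CohortTable) -> pd.DataFrame:
    """Flatten a cohort to the on-disk schema (all cells as strings)."""
    records = []
    for patient, outcome in cohort.rows:
        for idx, target in enumerate(patient.resections, start=1):
            rec = {
                "patient_id": patient.patient_id,
                "resection_index": str(idx),
                "age_years": str(patient.age_years),
                "sex": patient.sex,
                "bmi": _fmt_float(patient.bmi),
                "asa": str(patient.asa),
                "child_pugh": patient.child_pugh,
                "platelets_1e9_per_L": _fmt_float(patient.platelets_1e9_per_L),
                "liver_histology": patient.liver_histology,
                "approach": patient.approach,
                "resection_type": target.resection_type,
                "segments": ";".join(sorted(target.segments, key=_segment_sort_key)),
                "tumor_size_cm": _fmt_float(target.tumor_size_cm),
                "operative_time_min": str(outcome.operative_time_min),
                "blood_loss_ml": str(outcome.blood_loss_ml),
                "satava_grade": outcome.satava_grade,
                "clavien_dindo": str(outcome.clavien_dindo),
                "los_days": str(outcome.los_days),
                "margin": outcome.margin,
            }
            for f in _BOOL_PATIENT_FIELDS:
                rec[f] = "1" if getattr(patient, f) else "0"
            for f in _BOOL_OUTCOME_FIELDS:
                rec[f] = "1" if getattr(outcome, f) else "0"
            rec["malignant"] = "1" if target.malignant else "0"
            rec["proximity_major_vessels"] = "1" if target.proximity_major_vessels else "0"
            records.append(rec)
    return pd.DataFrame.from_records(records, columns=list(COHORT_COLUMNS))


def write_cohort(cohort: CohortTable, path) -> str:
    """Write a cohort CSV such that ``read_cohort`` reproduces it exactly."""
    frame = cohort_to_frame(cohort)
    frame.to_csv(path, index=False, lineterminator="\n")
    return str(path)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def _pct(count: int, n: int) -> float:
    """Percentage to one decimal, half-up."""
    return float(
        (Decimal(100 * count) / Decimal(n)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def _first_target(patient: PatientRecord) -> ResectionTarget:
    return patient.resections[0]


# (variable, level, predicate over (patient, outcome)) in presentation order.
_SUMMARY_SPEC = [
    ("age", "<65 years", lambda p, o: p.age_years < 65),
    ("age", ">=65 years", lambda p, o: p.age_years >= 65),
    ("sex", "male", lambda p, o: p.sex == "M"),
    ("sex", "female", lambda p, o: p.sex == "F"),
    ("bmi", "<25", lambda p, o: p.bmi < 25),
    ("bmi", ">=25", lambda p, o: p.bmi >= 25),
    ("asa", "1-2", lambda p, o: p.asa <= 2),
    ("asa", "3-4", lambda p, o: p.asa >= 3),
    ("cardiologic_comorbidity", "no", lambda p, o: not p.comorb_cardiologic),
    ("cardiologic_comorbidity", "yes", lambda p, o: p.comorb_cardiologic),
    ("vascular_comorbidity", "no", lambda p, o: not p.comorb_vascular),
    ("vascular_comorbidity", "yes", lambda p, o: p.comorb_vascular),
    ("diabetes", "no", lambda p, o: not p.comorb_diabetes),
    ("diabetes", "yes", lambda p, o: p.comorb_diabetes),
    ("respiratory_comorbidity", "no", lambda p, o: not p.comorb_respiratory),
    ("respiratory_comorbidity", "yes", lambda p, o: p.comorb_respiratory),
    ("neurologic_comorbidity", "no", lambda p, o: not p.comorb_neurologic),
    ("neurologic_comorbidity", "yes", lambda p, o: p.comorb_neurologic),
    ("chronic_kidney_disease", "no", lambda p, o: not p.comorb_ckd),
    ("chronic_kidney_disease", "yes", lambda p, o: p.comorb_ckd),
    ("liver_histology", "healthy", lambda p, o: p.liver_histology == "healthy"),
    ("liver_histology", "steatosis", lambda p, o: p.liver_histology == "steatosis"),
    ("liver_histology", "cirrhosis", lambda p, o: p.liver_histology == "cirrhosis"),
    ("portal_hypertension", "no", lambda p, o: not p.portal_hypertension),
    ("portal_hypertension", "yes", lambda p, o: p.portal_hypertension),
    ("platelets", "<=100e9/L", lambda p, o: p.platelets_1e9_per_L <= 100),
    ("platelets", ">100e9/L", lambda p, o: p.platelets_1e9_per_L > 100),
    ("neoadjuvant_chemotherapy", "no", lambda p, o: not p.neoadjuvant_chemotherapy),
    ("neoadjuvant_chemotherapy", "yes", lambda p, o: p.neoadjuvant_chemotherapy),
    ("child_pugh", "A", lambda p, o: p.child_pugh == "A"),
    ("child_pugh", "B", lambda p, o: p.child_pugh == "B"),
    ("malignant_disease", "no", lambda p, o: not any(t.malignant for t in p.resections)),
    ("malignant_disease", "yes", lambda p, o: any(t.malignant for t in p.resections)),
    ("operative_time", "<=240 min", lambda p, o: o.operative_time_min <= 240),
    ("operative_time", ">240 min", lambda p, o: o.operative_time_min > 240),
    ("blood_loss", "<=500 ml", lambda p, o: o.blood_loss_ml <= 500),
    ("blood_loss", ">500 ml", lambda p, o: o.blood_loss_ml > 500),
    ("conversion", "no", lambda p, o: not o.conversion),
    ("conversion", "yes", lambda p, o: o.conversion),
    ("transfusion", "no", lambda p, o: not o.transfusion),
    ("transfusion", "yes", lambda p, o: o.transfusion),
    ("intraoperative_events", "none", lambda p, o: o.satava_grade == "none"),
    ("intraoperative_events", "I", lambda p, o: o.satava_grade == "I"),
    ("intraoperative_events", "II", lambda p, o: o.satava_grade == "II"),
    ("intraoperative_events", "III", lambda p, o: o.satava_grade == "III"),
    ("complications", "none", lambda p, o: o.clavien_dindo == 0),
    ("complications", "clavien_dindo_1_2", lambda p, o: 1 <= o.clavien_dindo <= 2),
    ("complications", "clavien_dindo_ge3", lambda p, o: o.clavien_dindo >= 3),
    ("length_of_stay", "<=5 days", lambda p, o: o.los_days <= 5),
    ("length_of_stay", ">5 days", lambda p, o: o.los_days > 5),
    ("mortality_90d", "yes", lambda p, o: o.mortality_90d),
    ("readmission_90d", "yes", lambda p, o: o.readmission_90d),
    ("margin", "R0", lambda p, o: o.margin == "R0"),
    ("margin", "R1", lambda p, o: o.margin == "R1"),
]


def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Count/percentage table of the standard baseline and outcome variables.

    Returns a frame with columns ``variable``, ``level``, ``count``,
    ``percent`` (one decimal, half-up) and ``display`` (``"28 (8.1)"``).
    """
    n = len(cohort)
    if n == 0:
        raise EmptyCohortError("cannot summarize an empty cohort")
    out = []
    for variable, level, pred in _SUMMARY_SPEC:
        count = sum(1 for p, o in cohort.rows if pred(p, o))
        pct = _pct(count, n)
        out.append(
            {
                "variable": variable,
                "level": level,
                "count": count,
                "percent": pct,
                "display": f"{count} ({pct})",
            }
        )
    return pd.DataFrame(out)
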