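"""The four laparoscopic liver resection difficulty scores.

Each score is a rule-based point scheme mapping patient, tumor and resection
features to a difficulty class:

* **Halls** (Southampton): resection extent, tumor size/type, surgical
  history; 0–15 points, four classes.
* **Hasegawa**: resection type, tumor location, BMI, platelet count; 0–7
  points, three classes.
* **Kawaguchi** (IMM): resection type/location only; three groups.
* **Iwate** (updated Ban, Morioka consensus): size, location, extent, vessel
  proximity, liver function, hybrid approach; 0–12 points, four classes.

When a procedure involved several resections, each score is evaluated on the
most challenging target, i.e. the per-score maximum over targets.  For
cross-score comparison the two four-class systems (Halls, Iwate) are
collapsed to three ordinal levels by merging their two highest classes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import MAJOR_RESECTION_TYPES, PatientRecord, ResectionTarget
from .segments import DEFAULT_SEGMENT_CONFIG, SegmentConfig, is_contiguous, whole_segments

__all__ = [
    "ScorePanel",
    "is_major_resection",
    "halls_score",
    "halls_class",
    "hasegawa_score",
    "hasegawa_class",
    "kawaguchi_group",
    "iwate_score",
    "iwate_class",
    "score_panel",
    "collapse_halls",
    "collapse_hasegawa",
    "collapse_kawaguchi",
    "collapse_iwate",
]

HALLS_CLASSES = ("low", "moderate", "high", "extremely_high")
HASEGAWA_CLASSES = ("low", "medium", "high")
KAWAGUCHI_GROUPS = ("I", "II", "III")
IWATE_CLASSES = ("low", "intermediate", "advanced", "expert")


def is_major_resection(target: ResectionTarget) -> bool:
    """Brisbane major hepatectomy: >=3 contiguous segments, or a hemi-/
    extended/central hepatectomy by name."""
    if target.resection_type in MAJOR_RESECTION_TYPES:
        return True
    return len(whole_segments(target.segments)) >= 3 and is_contiguous(target.segments)


# ---------------------------------------------------------------------------
# Halls
# ---------------------------------------------------------------------------


def halls_score(
    patient: PatientRecord,
    target: ResectionTarget,
    config: SegmentConfig = DEFAULT_SEGMENT_CONFIG,
) -> int:
    """Halls difficulty points for one resection target.

    Components: 4 points for a major resection; 2 points for an anatomical
    resection of one or two segments including a posterosuperior segment;
    tumor size 3–5 cm 2 points, >5 cm 3 points; malignant tumor 2 points;
    previous open liver resection 5 points; neoadjuvant chemotherapy 1 point.
    """
    pts = 0
    if is_major_resection(target):
        pts += 4
    elif target.resection_type != "wedge" and len(whole_segments(target.segments)) <= 2:
        # small anatomical resection; the 2-point tier requires PS involvement
        # under the literal parse (configurable)
        if not config.halls_requires_posterosuperior or any(
            config.is_posterosuperior(s) for s in target.segments
        ):
            pts += 2
    size = target.tumor_size_cm
    if size > 5:
        pts += 3
    elif size >= 3:
        pts += 2
    if target.malignant:
        pts += 2
    if patient.previous_open_liver_resection:
        pts += 5
    if patient.neoadjuvant_chemotherapy:
        pts += 1
    return pts


def halls_class(score: int, config: SegmentConfig = DEFAULT_SEGMENT_CONFIG) -> str:
    """Halls class bins: low (<=2), moderate (3–5), high (6–9), extremely
    high (10–15).  The published bins skip score 2; it falls in "low"."""
    if not 0 <= score <= 15:
        raise ValueError(f"Halls score out of range 0..15: {score}")
    if score <= config.halls_low_max:
        return "low"
    if score <= 5:
        return "moderate"
    if score <= 9:
        return "high"
    return "extremely_high"


# ---------------------------------------------------------------------------
# Hasegawa
# ---------------------------------------------------------------------------


def _hasegawa_type_points(target: ResectionTarget) -> int:
    if is_major_resection(target):
        return 3
    if target.resection_type in ("wedge", "left_lateral_sectionectomy"):
        return 0
    # anatomical segmentectomy and other small anatomical resections
    return 2


def hasegawa_score(
    patient: PatientRecord,
    target: ResectionTarget,
    config: SegmentConfig = DEFAULT_SEGMENT_CONFIG,
) -> int:
    """Hasegawa difficulty points: resection type (0/2/3) + tumor location
    (max per-segment points) + BMI >= 30 (1) + platelets <= 100e9/L (1)."""
    pts = _hasegawa_type_points(target)
    pts += max(config.hasegawa_location_points[s] for s in target.segments)
    if patient.bmi >= 30:
        pts += 1
    if patient.platelets_1e9_per_L <= 100:
        pts += 1
    return pts


def hasegawa_class(score: int) -> str:
    """Hasegawa class bins: low (<=1), medium (2–3), high (>=4)."""
    if not 0 <= score <= 7:
        raise ValueError(f"Hasegawa score out of range 0..7: {score}")
    if score <= 1:
        return "low"
    if score <= 3:
        return "medium"
    return "high"


# ---------------------------------------------------------------------------
# Kawaguchi
# ---------------------------------------------------------------------------


def kawaguchi_group(
    target: ResectionTarget, config: SegmentConfig = DEFAULT_SEGMENT_CONFIG
) -> str:
    """Kawaguchi (IMM) difficulty group.

    I: wedge resections and left lateral sectionectomy.
    II: left hepatectomy and anterolateral anatomical segmentectomy.
    III: posterosuperior segmentectomy, right/central hepatectomy,
    extended hepatectomy.
    """
    rt = target.resection_type
    if rt in ("wedge", "left_lateral_sectionectomy"):
        return "I"
    if rt == "left_hepatectomy":
        return "II"
    if rt in ("right_hepatectomy", "central_hepatectomy", "extended_hepatectomy"):
        return "III"
    # anatomical segmentectomy / other sectionectomy: split on PS involvement
    if any(config.is_posterosuperior(s) for s in target.segments):
        return "III"
    return "II"


# ---------------------------------------------------------------------------
# Iwate
# ---------------------------------------------------------------------------

_IWATE_EXTENT_POINTS = {
    "wedge": 0,
    "left_lateral_sectionectomy": 2,
    "anatomical_segmentectomy": 3,
    # "sectionectomy and more"
    "sectionectomy_other": 4,
    "left_hepatectomy": 4,
    "right_hepatectomy": 4,
    "central_hepatectomy": 4,
    "extended_hepatectomy": 4,
}


def iwate_score(
    patient: PatientRecord,
    target: ResectionTarget,
    config: SegmentConfig = DEFAULT_SEGMENT_CONFIG,
) -> int:
    """Iwate difficulty points.

    Tumor size >= 3 cm 1 point; location 1–3 (anterolateral) or 4–5
    (posterosuperior) points, maximum over involved segments; extent 0
    (wedge) / 2 (left lateral sectionectomy) / 3 (segmentectomy) / 4
    (sectionectomy and more); proximity to major vessels 1 point;
    Child–Pugh B 1 point; hybrid/hand-assisted technique −1 point.
    The total is clamped at 0 from below.
    """
    pts = 0
    if target.tumor_size_cm >= 3:
        pts += 1
    pts += max(config.iwate_location_weights[s] for s in target.segments)
    pts += _IWATE_EXTENT_POINTS[target.resection_type]
    if target.proximity_major_vessels:
        pts += 1
    if patient.child_pugh == "B":
        pts += 1
    if patient.approach == "hybrid_or_hand_assisted":
        pts -= 1
    return max(pts, 0)


def iwate_class(score: int) -> str:
    """Iwate class bins: low (0–3), intermediate (4–6), advanced (7–9),
    expert (10–12).  The published bins start at 1; the attainable score 0
    (hybrid adjustment) maps to "low"."""
    if not 0 <= score <= 12:
        raise ValueError(f"Iwate score out of range 0..12: {score}")
    if score <= 3:
        return "low"
    if score <= 6:
        return "intermediate"
    return "advanced" if score <= 9 else "expert"


# ---------------------------------------------------------------------------
# Collapsing and the per-patient panel
# ---------------------------------------------------------------------------


def collapse_halls(cls: str) -> int:
    """Merge Halls high / extremely high into one top level."""
    return {"low": 1, "moderate": 2, "high": 3, "extremely_high": 3}[cls]


def collapse_hasegawa(cls: str) -> int:
    return {"low": 1, "medium": 2, "high": 3}[cls]


def collapse_kawaguchi(group: str) -> int:
    return {"I": 1, "II": 2, "III": 3}[group]


def collapse_iwate(cls: str) -> int:
    """Merge Iwate advanced / expert into one top level."""
    return {"low": 1, "intermediate": 2, "advanced": 3, "expert": 3}[cls]


@dataclass(frozen=True)
class ScorePanel:
    """All four difficulty scores for one patient."""

    halls_score: int
    halls_class: str
    hasegawa_score: int
    hasegawa_class: str
    kawaguchi_group: str
    iwate_score: int
    iwate_class: str
    halls_collapsed: int
    hasegawa_collapsed: int
    kawaguchi_collapsed: int
    iwate_collapsed: int

    COLUMNS = (
        "halls_score",
        "halls_class",
        "hasegawa_score",
        "hasegawa_class",
        "kawaguchi_group",
        "iwate_score",
        "iwate_class",
        "halls_collapsed",
        "hasegawa_collapsed",
        "kawaguchi_collapsed",
        "iwate_collapsed",
    )


def score_panel(
    patient: PatientRecord, config: SegmentConfig = DEFAULT_SEGMENT_CONFIG
) -> ScorePanel:
    """Score one patient on all four systems.

    With several resection targets each score is computed per target and the
    maximum taken independently per system ("the most challenging one").
    """
    halls = max(halls_score(patient, t, config) for t in patient.resections)
    haseg = max(hasegawa_score(patient, t, config) for t in patient.resections)
    kawa = max(
        (kawaguchi_group(t, config) for t in patient.resections),
        key=KAWAGUCHI_GROUPS.index,
    )
    iwate = max(iwate_score(patient, t, config) for t in patient.resections)
    h_cls = halls_class(halls, config)
    hs_cls = hasegawa_class(haseg)
    iw_cls = iwate_class(iwate)
    return ScorePanel(
        halls_score=halls,
        halls_class=h_cls,
        hasegawa_score=haseg,
        hasegawa_class=hs_cls,
        kawaguchi_group=kawa,
        iwate_score=iwate,
        iwate_class=iw_cls,
        halls_collapsed=collapse_halls(h_cls),
        hasegawa_collapsed=collapse_hasegawa(hs_cls),
        kawaguchi_collapsed=collapse_kawaguchi(kawa),
        iwate_collapsed=collapse_iwate(iw_cls),
    )
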