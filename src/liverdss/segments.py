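"""Couinaud segment vocabulary, adjacency, and per-score segment configuration.

The liver is modelled as the eight Couinaud segments, with segment 4 split
into 4a (cranial) and 4b (caudal) because the posterosuperior/anterolateral
dichotomy — which drives several scoring rules — differs between the two
sub-segments: 4a sits under the diaphragm next to the hepatic veins, 4b is
anterior and easily reached laparoscopically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Mapping

__all__ = [
    "SEGMENTS",
    "POSTEROSUPERIOR_DEFAULT",
    "SegmentConfig",
    "DEFAULT_SEGMENT_CONFIG",
    "normalize_segments",
    "whole_segments",
    "is_contiguous",
]

#: The nine-label segment vocabulary (segment 4 split into 4a/4b).
SEGMENTS: tuple[str, ...] = ("1", "2", "3", "4a", "4b", "5", "6", "7", "8")

#: Conventional posterosuperior segments: deep, diaphragmatic, hardest
#: laparoscopic access.
POSTEROSUPERIOR_DEFAULT: FrozenSet[str] = frozenset({"1", "4a", "7", "8"})

# Whole-segment (Brisbane-level) anatomical adjacency.  4a/4b merge into "4":
# contiguity for the major-hepatectomy rule is a statement about whole
# segments, not sub-segments.
_WHOLE_ADJACENCY: Mapping[str, frozenset[str]] = {
    "1": frozenset({"2", "4", "7", "8"}),
    "2": frozenset({"1", "3", "4"}),
    "3": frozenset({"2", "4"}),
    "4": frozenset({"1", "2", "3", "5", "8"}),
    "5": frozenset({"4", "6", "8"}),
    "6": frozenset({"5", "7"}),
    "7": frozenset({"1", "6", "8"}),
    "8": frozenset({"1", "4", "5", "7"}),
}

# Default Iwate-style per-segment location weights, adapted from the published
# consensus table to the 4a/4b split.  Anterolateral weights lie in [1, 3],
# posterosuperior in [4, 5].
_IWATE_WEIGHTS_DEFAULT: Mapping[str, int] = {
    "1": 4,
    "2": 2,
    "3": 1,
    "4a": 4,
    "4b": 3,
    "5": 3,
    "6": 2,
    "7": 5,
    "8": 5,
}

# Hasegawa location points: segments 7-8 two points, 5-6 one point,
# 2-3-4 zero.  Segment 1 is not covered by that enumeration; it is treated as
# difficult (2 points) by default, like the posterosuperior segments.
_HASEGAWA_POINTS_DEFAULT: Mapping[str, int] = {
    "1": 2,
    "2": 0,
    "3": 0,
    "4a": 0,
    "4b": 0,
    "5": 1,
    "6": 1,
    "7": 2,
    "8": 2,
}


def normalize_segments(labels: Iterable[str], plain_segment4: str = "4b") -> frozenset[str]:
    """Validate segment labels against the vocabulary.

    A plain ``"4"`` is accepted and expanded to ``plain_segment4``
    (default ``"4b"``, the anterolateral sub-segment).

    Raises
    ------
    ValueError
        If a label is outside the vocabulary or the set is empty.
    """
    out = set()
    for raw in labels:
        label = str(raw).strip()
        if label == "4":
            label = plain_segment4
        if label not in SEGMENTS:
            raise ValueError(f"unknown Couinaud segment label: {raw!r}")
        out.add(label)
    if not out:
        raise ValueError("segment set must be non-empty")
    return frozenset(out)


def whole_segments(labels: Iterable[str]) -> frozenset[str]:
    """Collapse 4a/4b to whole segment 4."""
    return frozenset("4" if s in ("4a", "4b") else s for s in labels)


def is_contiguous(labels: Iterable[str]) -> bool:
    """True when the involved whole segments form a connected anatomical block."""
    nodes = whole_segments(labels)
    if not nodes:
        return False
    start = next(iter(nodes))
    seen = {start}
    stack = [start]
    while stack:
        for nb in _WHOLE_ADJACENCY[stack.pop()]:
            if nb in nodes and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen == nodes


@dataclass(frozen=True)
class SegmentConfig:
    """Tunable segment-level rules shared by the four difficulty scores.

    Parameters
    ----------
    posterosuperior
        Segments counted as posterosuperior (default ``{1, 4a, 7, 8}``).
    iwate_location_weights
        Per-segment Iwate location points; anterolateral segments must carry
        1–3 points, posterosuperior segments 4–5.
    hasegawa_location_points
        Per-segment Hasegawa location points.
    halls_requires_posterosuperior
        Whether the Halls 2-point tier for 1–2-segment anatomical resections
        demands a posterosuperior segment (literal reading) or applies to
        every small anatomical resection.
    halls_low_max
        Upper score bound of the Halls "low" class (the published bins skip
        score 2; it is folded into "low" by default).
    plain_segment4
        Sub-segment a bare input label ``"4"`` expands to.
    """

    posterosuperior: FrozenSet[str] = POSTEROSUPERIOR_DEFAULT
    iwate_location_weights: Mapping[str, int] = field(
        default_factory=lambda: dict(_IWATE_WEIGHTS_DEFAULT)
    )
    hasegawa_location_points: Mapping[str, int] = field(
        default_factory=lambda: dict(_HASEGAWA_POINTS_DEFAULT)
    )
    halls_requires_posterosuperior: bool = True
    halls_low_max: int = 2
    plain_segment4: str = "4b"

    def __post_init__(self) -> None:
        unknown = set(self.posterosuperior) - set(SEGMENTS)
        if unknown:
            raise ValueError(f"posterosuperior set has unknown labels: {sorted(unknown)}")
        for name, table in (
            ("iwate_location_weights", self.iwate_location_weights),
            ("hasegawa_location_points", self.hasegawa_location_points),
        ):
            missing = set(SEGMENTS) - set(table)
            if missing:
                raise ValueError(f"{name} missing segments: {sorted(missing)}")
        for seg in SEGMENTS:
            w = self.iwate_location_weights[seg]
            lo, hi = (4, 5) if seg in self.posterosuperior else (1, 3)
            if not lo <= w <= hi:
                raise ValueError(
                    f"Iwate weight for segment {seg} must be in [{lo}, {hi}], got {w}"
                )
        if self.plain_segment4 not in ("4a", "4b"):
            raise ValueError("plain_segment4 must be '4a' or '4b'")

    def is_posterosuperior(self, label: str) -> bool:
        return label in self.posterosuperior


DEFAULT_SEGMENT_CONFIG = SegmentConfig()
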