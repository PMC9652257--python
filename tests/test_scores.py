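"""Score engines: worked examples, brute-force extrema, monotonicity."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, strategies as st

from liverdss import (
    SegmentConfig,
    halls_class,
    halls_score,
    hasegawa_class,
    hasegawa_score,
    iwate_class,
    iwate_score,
    kawaguchi_group,
    score_panel,
)
from liverdss.scores import (
    collapse_halls,
    collapse_hasegawa,
    collapse_iwate,
    collapse_kawaguchi,
    is_major_resection,
)
from liverdss.segments import SEGMENTS

from conftest import _make_patient, _make_target

# Representative segment sets per resection type, spanning the discrete
# feature domain (anterolateral/posterosuperior singletons, pairs, and the
# fixed anatomical sets).
SEGMENT_CHOICES = {
    "wedge": [{s} for s in SEGMENTS],
    "anatomical_segmentectomy": [{s} for s in SEGMENTS]
    + [{"2", "3"}, {"7", "8"}, {"5", "6"}, {"4a", "4b"}, {"5", "6", "7"}],
    "left_lateral_sectionectomy": [{"2", "3"}],
    "sectionectomy_other": [{"5", "8"}, {"6", "7"}],
    "left_hepatectomy": [{"2", "3", "4a", "4b"}],
    "right_hepatectomy": [{"5", "6", "7", "8"}],
    "central_hepatectomy": [{"4a", "4b", "5", "8"}],
    "extended_hepatectomy": [{"2", "3", "4a", "4b", "5", "8"}, {"4a", "4b", "5", "6", "7", "8"}],
}

SIZES = (2.0, 4.0, 6.0)  # <3 cm, 3-5 cm, >5 cm


def iter_targets():
    for rtype, seg_sets in SEGMENT_CHOICES.items():
        for segs in seg_sets:
            for size in SIZES:
                for malignant in (False, True):
                    for vessels in (False, True):
                        yield _make_target(
                            resection_type=rtype,
                            segments=frozenset(segs),
                            tumor_size_cm=size,
                            malignant=malignant,
                            proximity_major_vessels=vessels,
                        )


def iter_patients():
    """Cross the target domain with the patient-level scored features."""
    for target in iter_targets():
        for prev, chemo, cp, bmi, plt, approach in itertools.product(
            (False, True),
            (False, True),
            ("A", "B"),
            (24.0, 31.0),
            (200.0, 90.0),
            ("pure_laparoscopic", "hybrid_or_hand_assisted"),
        ):
            yield _make_patient(
                previous_open_liver_resection=prev,
                neoadjuvant_chemotherapy=chemo,
                child_pugh=cp,
                bmi=bmi,
                platelets_1e9_per_L=plt,
                approach=approach,
                resections=(target,),
            )


class TestWorkedExamples:
    def test_halls_maximum_patient(self):
        p = _make_patient(
            previous_open_liver_resection=True,
            neoadjuvant_chemotherapy=True,
            resections=(
                _make_target(
                    resection_type="right_hepatectomy",
                    segments=frozenset({"5", "6", "7", "8"}),
                    tumor_size_cm=6.0,
                    malignant=True,
                ),
            ),
        )
        assert halls_score(p, p.resections[0]) == 15

    def test_halls_no_criterion_met(self):
        p = _make_patient()
        assert halls_score(p, p.resections[0]) == 0

    def test_halls_posterosuperior_segmentectomy(self):
        t = _make_target(
            resection_type="anatomical_segmentectomy",
            segments=frozenset({"7"}),
            tumor_size_cm=4.0,
            malignant=True,
        )
        assert halls_score(_make_patient(resections=(t,)), t) == 6

    def test_halls_anterolateral_segmentectomy_scores_zero_for_resection(self):
        t = _make_target(
            resection_type="anatomical_segmentectomy", segments=frozenset({"3"})
        )
        assert halls_score(_make_patient(resections=(t,)), t) == 0

    @pytest.mark.parametrize(
        "score,expected",
        [(0, "low"), (1, "low"), (2, "low"), (3, "moderate"), (5, "moderate"),
         (6, "high"), (9, "high"), (10, "extremely_high"), (15, "extremely_high")],
    )
    def test_halls_bins(self, score, expected):
        assert halls_class(score) == expected

    def test_hasegawa_maximum_patient(self):
        t = _make_target(
            resection_type="right_hepatectomy",
            segments=frozenset({"5", "6", "7", "8"}),
        )
        p = _make_patient(bmi=31.0, platelets_1e9_per_L=90.0, resections=(t,))
        assert hasegawa_score(p, t) == 7

    def test_hasegawa_wedge_s3_scores_zero(self):
        t = _make_target(segments=frozenset({"3"}))
        assert hasegawa_score(_make_patient(resections=(t,)), t) == 0

    def test_hasegawa_segmentectomy_s6(self):
        t = _make_target(
            resection_type="anatomical_segmentectomy", segments=frozenset({"6"})
        )
        assert hasegawa_score(_make_patient(resections=(t,)), t) == 3

    @pytest.mark.parametrize(
        "score,expected",
        [(0, "low"), (1, "low"), (2, "medium"), (3, "medium"), (4, "high"), (7, "high")],
    )
    def test_hasegawa_bins(self, score, expected):
        assert hasegawa_class(score) == expected

    @pytest.mark.parametrize(
        "rtype,segs,expected",
        [
            ("left_lateral_sectionectomy", {"2", "3"}, "I"),
            ("wedge", {"8"}, "I"),
            ("right_hepatectomy", {"5", "6", "7", "8"}, "III"),
            ("anatomical_segmentectomy", {"2"}, "II"),
            ("anatomical_segmentectomy", {"8"}, "III"),
            ("left_hepatectomy", {"2", "3", "4a", "4b"}, "II"),
            ("central_hepatectomy", {"4a", "4b", "5", "8"}, "III"),
            ("extended_hepatectomy", {"4a", "4b", "5", "6", "7", "8"}, "III"),
            ("sectionectomy_other", {"6", "7"}, "III"),
        ],
    )
    def test_kawaguchi_groups(self, rtype, segs, expected):
        t = _make_target(resection_type=rtype, segments=frozenset(segs))
        assert kawaguchi_group(t) == expected

    def test_iwate_maximum_patient(self):
        t = _make_target(
            resection_type="right_hepatectomy",
            segments=frozenset({"5", "6", "7", "8"}),
            tumor_size_cm=4.0,
            proximity_major_vessels=True,
        )
        p = _make_patient(child_pugh="B", resections=(t,))
        assert iwate_score(p, t) == 12

    def test_iwate_hybrid_wedge_clamped_at_zero(self):
        t = _make_target(segments=frozenset({"3"}))  # weight-1 anterolateral
        p = _make_patient(approach="hybrid_or_hand_assisted", resections=(t,))
        assert iwate_score(p, t) == 0

    def test_iwate_lls_is_two_plus_segment_weight(self):
        config = SegmentConfig()
        t = _make_target(
            resection_type="left_lateral_sectionectomy", segments=frozenset({"3"})
        )
        p = _make_patient(resections=(t,))
        assert iwate_score(p, t) == 2 + config.iwate_location_weights["3"]

    @pytest.mark.parametrize(
        "score,expected",
        [(0, "low"), (1, "low"), (3, "low"), (4, "intermediate"), (6, "intermediate"),
         (7, "advanced"), (9, "advanced"), (10, "expert"), (12, "expert")],
    )
    def test_iwate_bins(self, score, expected):
        assert iwate_class(score) == expected

    @pytest.mark.parametrize("func,bad", [(halls_class, 16), (halls_class, -1),
                                          (hasegawa_class, 8), (iwate_class, 13)])
    def test_out_of_range_scores_rejected(self, func, bad):
        with pytest.raises(ValueError):
            func(bad)


@pytest.fixture(scope="module")
def all_panels():
    return [score_panel(p) for p in iter_patients()]


class TestBruteForceExtrema:
    """Enumerate the discrete feature domain and check score ranges."""

    def test_halls_range(self, all_panels):
        scores = [p.halls_score for p in all_panels]
        assert max(scores) == 15
        assert min(scores) == 0

    def test_iwate_range(self, all_panels):
        scores = [p.iwate_score for p in all_panels]
        assert max(scores) == 12
        assert min(scores) == 0

    def test_hasegawa_range(self, all_panels):
        scores = [p.hasegawa_score for p in all_panels]
        assert max(scores) == 7
        assert min(scores) == 0

    def test_classes_consistent_with_scores(self, all_panels):
        for panel in all_panels:
            assert panel.halls_class == halls_class(panel.halls_score)
            assert panel.hasegawa_class == hasegawa_class(panel.hasegawa_score)
            assert panel.iwate_class == iwate_class(panel.iwate_score)


def test_brisbane_major_rule():
    major = _make_target(
        resection_type="anatomical_segmentectomy", segments=frozenset({"5", "6", "7"})
    )
    assert is_major_resection(major)
    noncontiguous = _make_target(
        resection_type="anatomical_segmentectomy", segments=frozenset({"2", "3", "7"})
    )
    assert not is_major_resection(noncontiguous)
    sub_segments = _make_target(
        resection_type="anatomical_segmentectomy", segments=frozenset({"4a", "4b", "5"})
    )
    # 4a+4b is one whole segment: only two segments involved
    assert not is_major_resection(sub_segments)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

_target_strategy = st.builds(
    _make_target,
    resection_type=st.sampled_from(list(SEGMENT_CHOICES)),
    segments=st.sets(st.sampled_from(SEGMENTS), min_size=1, max_size=3).map(frozenset),
    tumor_size_cm=st.sampled_from(SIZES),
    malignant=st.booleans(),
    proximity_major_vessels=st.booleans(),
)

_patient_strategy = st.builds(
    lambda t, prev, chemo, cp, bmi, plt, approach: _make_patient(
        previous_open_liver_resection=prev,
        neoadjuvant_chemotherapy=chemo,
        child_pugh=cp,
        bmi=bmi,
        platelets_1e9_per_L=plt,
        approach=approach,
        resections=(t,),
    ),
    t=_target_strategy,
    prev=st.booleans(),
    chemo=st.booleans(),
    cp=st.sampled_from(["A", "B"]),
    bmi=st.sampled_from([24.0, 31.0]),
    plt=st.sampled_from([200.0, 90.0]),
    approach=st.sampled_from(["pure_laparoscopic", "hybrid_or_hand_assisted"]),
)


def _all_scores(patient):
    t = patient.resections[0]
    return (
        halls_score(patient, t),
        hasegawa_score(patient, t),
        iwate_score(patient, t),
    )


@given(_patient_strategy)
def test_point_scoring_features_never_decrease_scores(patient):
    """Turning on any point-scoring feature is monotone non-decreasing."""
    import dataclasses

    base = _all_scores(patient)
    t = patient.resections[0]
    variants = [
        dataclasses.replace(
            patient, resections=(dataclasses.replace(t, malignant=True),)
        ),
        dataclasses.replace(
            patient, resections=(dataclasses.replace(t, proximity_major_vessels=True),)
        ),
        dataclasses.replace(patient, previous_open_liver_resection=True),
        dataclasses.replace(patient, neoadjuvant_chemotherapy=True),
        dataclasses.replace(patient, child_pugh="B"),
        dataclasses.replace(patient, bmi=31.0),
        dataclasses.replace(patient, platelets_1e9_per_L=90.0),
    ]
    if t.tumor_size_cm < 6.0:
        bigger = 4.0 if t.tumor_size_cm < 3.0 else 6.0
        variants.append(
            dataclasses.replace(
                patient, resections=(dataclasses.replace(t, tumor_size_cm=bigger),)
            )
        )
    for variant in variants:
        for before, after in zip(base, _all_scores(variant)):
            assert after >= before


@given(_patient_strategy)
def test_hybrid_approach_lowers_iwate_by_exactly_one(patient):
    import dataclasses

    pure = dataclasses.replace(patient, approach="pure_laparoscopic")
    hybrid = dataclasses.replace(patient, approach="hybrid_or_hand_assisted")
    t = patient.resections[0]
    assert iwate_score(pure, t) - iwate_score(hybrid, t) == 1
    assert halls_score(pure, t) == halls_score(hybrid, t)
    assert hasegawa_score(pure, t) == hasegawa_score(hybrid, t)


def test_class_functions_total_and_weakly_increasing():
    for func, ordering, rng in (
        (halls_class, ("low", "moderate", "high", "extremely_high"), range(16)),
        (hasegawa_class, ("low", "medium", "high"), range(8)),
        (iwate_class, ("low", "intermediate", "advanced", "expert"), range(13)),
    ):
        indices = [ordering.index(func(s)) for s in rng]
        assert indices == sorted(indices)


def test_collapse_is_monotone_surjection():
    assert [collapse_halls(c) for c in ("low", "moderate", "high", "extremely_high")] == [1, 2, 3, 3]
    assert [collapse_iwate(c) for c in ("low", "intermediate", "advanced", "expert")] == [1, 2, 3, 3]
    assert [collapse_hasegawa(c) for c in ("low", "medium", "high")] == [1, 2, 3]
    assert [collapse_kawaguchi(g) for g in ("I", "II", "III")] == [1, 2, 3]


@given(st.lists(_target_strategy, min_size=1, max_size=4))
def test_panel_is_elementwise_max_over_targets(targets):
    import dataclasses

    patient = _make_patient(resections=tuple(targets))
    panel = score_panel(patient)
    singles = [
        score_panel(dataclasses.replace(patient, resections=(t,))) for t in targets
    ]
    assert panel.halls_score == max(s.halls_score for s in singles)
    assert panel.hasegawa_score == max(s.hasegawa_score for s in singles)
    assert panel.iwate_score == max(s.iwate_score for s in singles)
    assert panel.kawaguchi_collapsed == max(s.kawaguchi_collapsed for s in singles)


def test_duplicate_targets_are_idempotent(make_target, make_patient):
    t = make_target(resection_type="right_hepatectomy", segments=frozenset({"5", "6", "7", "8"}))
    one = score_panel(make_patient(resections=(t,)))
    two = score_panel(make_patient(resections=(t, t)))
    assert one == two


def test_multi_target_halls_from_most_challenging(make_target, make_patient):
    easy = make_target(segments=frozenset({"3"}), tumor_size_cm=1.0)
    hard = make_target(
        resection_type="right_hepatectomy",
        segments=frozenset({"5", "6", "7", "8"}),
        tumor_size_cm=6.0,
        malignant=True,
    )
    panel = score_panel(make_patient(resections=(easy, hard)))
    assert panel.halls_score == 9  # 4 major + 3 size + 2 malignant
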