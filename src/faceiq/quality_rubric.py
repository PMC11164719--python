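"""The adapted 6-level ordinal image-quality rubric.

An examiner records, per target image, a handful of structured judgements:
how many of the 15 standard FISWG facial components are unusable (bilateral
features count once; the optional components — scars, marks, alterations —
are excluded), what percentage of the face/head/neck area is overlaid or
artefacted, how visible small-scale detail (skin texture, luminance, fine
hair) is, and the colour depth of the image.  Each judgement maps to a
candidate score on the 1 (optimal) … 6 (insufficient for morphological
analysis) scale and the final score is the worst candidate — a conservative
rule: one disqualifying deficiency is enough.

Band conventions (the verbal definitions leave exact boundary percentages
open; half-open bands keep every value uniquely assigned and aligned with
the component-count bands):

==========  =================  ==================
score       unusable           overlay/artefact %
            components
==========  =================  ==================
1           0                  0
2           1                  (0, 5]
3           2–4                (5, 30)
4           5–9                [30, 65)
5           10–12              [65, 80)
6           ≥13                ≥80
==========  =================  ==================

Colour depth below 8 bits per channel is on its own sufficient for score 6.
The free-text resolution/sharpness/illumination "deficiency" wording of the
rubric is recorded as an advisory grade but does not determine the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Mapping, NamedTuple, Sequence, Union

from .exceptions import ConsistencyError, InvalidInputError

__all__ = [
    "DetailVisibility",
    "DeficiencyGrade",
    "QualityAssessment",
    "QualityScore",
    "MedianScore",
    "score_components",
    "score_overlay",
    "assess",
    "cohort_score_median",
    "N_STANDARD_COMPONENTS",
]

#: FISWG standard facial components entering the denominator (1-15).
N_STANDARD_COMPONENTS = 15


class DetailVisibility(str, Enum):
    """Visibility of small-scale facial features and skin structures."""

    DETAILED = "detailed"
    SOMEWHAT_UNCLEAR = "somewhat_unclear"
    LIMITED = "limited"
    ABSENT = "absent"


class DeficiencyGrade(str, Enum):
    """Advisory overall grade of resolution/sharpness/illumination."""

    EXCELLENT = "excellent"
    GOOD = "good"
    FEW_DEFICITS = "few_deficits"
    CLEAR_DEFICIENCIES = "clear_deficiencies"
    DEFICIENT = "deficient"


@dataclass(frozen=True)
class QualityAssessment:
    """Structured examiner inputs for one target image."""

    unusable_components: int
    overlay_artifact_percent: float
    small_scale_detail: DetailVisibility
    only_large_scale_describable: bool = False
    colour_depth_bits: int = 8
    deficiency_grade: DeficiencyGrade = DeficiencyGrade.EXCELLENT

    def __post_init__(self) -> None:
        if not 0 <= self.unusable_components <= N_STANDARD_COMPONENTS:
            raise InvalidInputError(
                f"unusable_components must be 0-{N_STANDARD_COMPONENTS}, "
                f"got {self.unusable_components}"
            )
        if not 0 <= self.overlay_artifact_percent <= 100:
            raise InvalidInputError(
                f"overlay_artifact_percent must be 0-100, "
                f"got {self.overlay_artifact_percent}"
            )
        if self.colour_depth_bits < 1:
            raise InvalidInputError("colour_depth_bits must be >= 1")
        if self.only_large_scale_describable:
            if self.small_scale_detail is not DetailVisibility.ABSENT:
                raise ConsistencyError(
                    "only_large_scale_describable requires small_scale_detail "
                    "to be 'absent'"
                )
            if self.unusable_components == 0:
                raise ConsistencyError(
                    "only_large_scale_describable contradicts zero unusable "
                    "components"
                )


@dataclass(frozen=True)
class QualityScore:
    """Final ordinal score plus the audit trail that produced it."""

    score: int
    triggered_criteria: List[str] = field(default_factory=list)
    per_criterion_scores: Dict[str, int] = field(default_factory=dict)
    advisory_deficiency_grade: DeficiencyGrade = DeficiencyGrade.EXCELLENT


def score_components(unusable: int) -> int:
    """Candidate score from the count of unusable FISWG components."""
    if not 0 <= unusable <= N_STANDARD_COMPONENTS:
        raise InvalidInputError(
            f"unusable component count must be 0-{N_STANDARD_COMPONENTS}, "
            f"got {unusable}"
        )
    if unusable == 0:
        return 1
    if unusable == 1:
        return 2
    if unusable <= 4:
        return 3
    if unusable <= 9:
        return 4
    if unusable <= 12:
        return 5
    return 6


def score_overlay(percent: float) -> int:
    """Candidate score from the overlay/artefact percentage of the face area."""
    if not 0 <= percent <= 100:
        raise InvalidInputError(f"overlay percent must be in [0, 100], got {percent}")
    if percent == 0:
        return 1
    if percent <= 5:
        return 2
    if percent < 30:
        return 3
    if percent < 65:
        return 4
    if percent < 80:
        return 5
    return 6


def _score_detail(detail: DetailVisibility, only_large_scale: bool) -> int:
    if detail is DetailVisibility.DETAILED:
        return 1
    if detail is DetailVisibility.SOMEWHAT_UNCLEAR:
        return 2
    if detail is DetailVisibility.LIMITED:
        return 4
    # absent: large-scale features still describable -> 5; nothing -> 6
    return 5 if only_large_scale else 6


def _score_colour_depth(bits: int) -> int:
    return 6 if bits < 8 else 1


def assess(assessment: QualityAssessment) -> QualityScore:
    """Map an examiner assessment to the final 1-6 quality score.

    Candidates are computed per criterion and the *maximum* (worst) wins;
    ``triggered_criteria`` lists every criterion attaining it.
    """
    candidates = {
        "unusable_components": score_components(assessment.unusable_components),
        "overlay_artifact_percent": score_overlay(
            assessment.overlay_artifact_percent
        ),
        "small_scale_detail": _score_detail(
            assessment.small_scale_detail,
            assessment.only_large_scale_describable,
        ),
        "colour_depth": _score_colour_depth(assessment.colour_depth_bits),
    }
    final = max(candidates.values())
    triggered = [name for name, s in candidates.items() if s == final]
    return QualityScore(
        score=final,
        triggered_criteria=triggered,
        per_criterion_scores=candidates,
        advisory_deficiency_grade=assessment.deficiency_grade,
    )


class MedianScore(NamedTuple):
    """Ordinal median; ``ambiguous`` marks an even split across two scores."""

    score: int
    ambiguous: bool


def cohort_score_median(
    counts: Union[Sequence[int], Mapping[int, int]]
) -> MedianScore:
    """Median quality score of a cohort given its score frequency table.

    ``counts`` is either a 6-element sequence (index 0 = score 1) or a
    mapping score → count.  For even totals whose two central order
    statistics differ, the lower one is reported with ``ambiguous=True``.
    """
    if isinstance(counts, Mapping):
        freq = [int(counts.get(s, 0)) for s in range(1, 7)]
    else:
        freq = [int(c) for c in counts]
        if len(freq) != 6:
            raise InvalidInputError(
                f"expected 6 score counts (scores 1-6), got {len(freq)}"
            )
    if any(c < 0 for c in freq):
        raise InvalidInputError("score counts must be non-negative")
    total = sum(freq)
    if total < 1:
        raise InvalidInputError("score frequency table is empty")

    def value_at(position: int) -> int:
        """Score at 1-based rank ``position`` in the sorted expansion."""
        cum = 0
        for score, c in enumerate(freq, start=1):
            cum += c
            if cum >= position:
                return score
        raise AssertionError("position beyond total")

    if total % 2 == 1:
        return MedianScore(value_at((total + 1) // 2), ambiguous=False)
    lo = value_at(total // 2)
    hi = value_at(total // 2 + 1)
    return MedianScore(lo, ambiguous=lo != hi)
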