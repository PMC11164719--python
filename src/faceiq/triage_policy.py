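"""Pre-comparison image triage.

Before any morphological facial comparison starts, each target image is
screened on three axes:

* **quality score** — a score of 6 (insufficient) always excludes the image;
  scores 1–2 are the only ones that proceed without caution;
* **face resolution** — a face-to-image pixel proportion (FIPP) below the
  threshold (default 6%) excludes the image; the 1–6% band additionally
  carries a further-research flag because no validated threshold exists
  inside it yet;
* **exposure** — a high underexposed ratio warns of false-positive risk
  (dark faces tempt examiners into over-claiming matches); a high
  overexposed ratio notes the opposite tendency towards false negatives.

Warnings never change the decision; they annotate it.  The decision is an
ordered outcome (proceed < caution < exclude) and is fully reconstructible
from the emitted reason identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Union

from .exceptions import IncompleteRecordError, InvalidInputError
from .histogram_metrics import ExposureSummary
from .imaging import FippResult
from .quality_rubric import QualityScore

__all__ = [
    "Decision",
    "TriageConfig",
    "TriageDecision",
    "triage",
    "decision_from_reasons",
    "EXCLUSION_REASONS",
]


class Decision(str, Enum):
    PROCEED = "proceed"
    CAUTION = "caution"
    EXCLUDE = "exclude"


#: Reasons that force exclusion; any other reason yields caution at most.
EXCLUSION_REASONS = frozenset({"quality_score_6", "fipp_below_threshold"})


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds driving the triage rules.

    ``fipp_threshold`` is the validated face-resolution floor (0.06).  The
    exposure warning levels are configurable extrapolations: cohort means
    put heavily underexposed material above ~0.32 and everything else below
    ~0.08, so the default UFR warning sits between those regimes.
    """

    fipp_threshold: float = 0.06
    ufr_warn: float = 0.20
    ofr_warn: float = 0.10
    fipp_research_floor: float = 0.01

    def __post_init__(self) -> None:
        for name in ("fipp_threshold", "ufr_warn", "ofr_warn", "fipp_research_floor"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidInputError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class TriageDecision:
    decision: Decision
    reasons: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)


def decision_from_reasons(reasons: List[str]) -> Decision:
    """Reconstruct the decision from reason identifiers alone (audit rule)."""
    if any(r in EXCLUSION_REASONS for r in reasons):
        return Decision.EXCLUDE
    if reasons:
        return Decision.CAUTION
    return Decision.PROCEED


def triage(
    score: Union[QualityScore, int, None],
    fipp: Union[FippResult, float, None],
    exposure: Optional[ExposureSummary],
    config: Optional[TriageConfig] = None,
) -> TriageDecision:
    """Triage one image from its score, face resolution and exposure.

    All three components must be present (computed for the same image);
    a missing one raises :class:`IncompleteRecordError` naming it.
    """
    cfg = config or TriageConfig()
    missing = [
        name
        for name, value in (("score", score), ("fipp", fipp), ("exposure", exposure))
        if value is None
    ]
    if missing:
        raise IncompleteRecordError(
            "triage record incomplete; missing: " + ", ".join(missing)
        )

    score_value = score.score if isinstance(score, QualityScore) else int(score)
    if not 1 <= score_value <= 6:
        raise InvalidInputError(f"quality score must be 1-6, got {score_value}")
    fipp_value = fipp.proportion if isinstance(fipp, FippResult) else float(fipp)
    if not 0 < fipp_value <= 1:
        raise InvalidInputError(f"FIPP must be in (0, 1], got {fipp_value}")

    reasons: List[str] = []
    warnings: List[str] = []
    if score_value == 6:
        reasons.append("quality_score_6")
    if fipp_value < cfg.fipp_threshold:
        reasons.append("fipp_below_threshold")
        if fipp_value >= cfg.fipp_research_floor:
            # 1-6% band: excluded conservatively, but flagged as the zone
            # where no validated cut-off exists yet.
            warnings.append("fipp_band_needs_further_research")
    if 3 <= score_value <= 5:
        reasons.append("intermediate_quality_score")
    if exposure.ufr > cfg.ufr_warn:
        warnings.append("underexposure_false_positive_risk")
    if exposure.ofr > cfg.ofr_warn:
        warnings.append("overexposure_false_negative_tendency")

    return TriageDecision(
        decision=decision_from_reasons(reasons),
        reasons=reasons,
        warnings=warnings,
    )
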