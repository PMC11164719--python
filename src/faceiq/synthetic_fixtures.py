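"""Synthetic face-like images and study tables for end-to-end testing.

The study's image corpus (a protected face database) cannot be shipped, so
this module fabricates stand-ins with *known* ground truth:

* :func:`make_image` paints a background at a distinct grey, fills an
  elliptical "face" inside the requested crop box with truncated-normal
  pixel noise, and then injects exact counts of dark (grey 0–9) and bright
  (grey 246–255) pixels into the box so the realized under-/over-exposure
  ratios hit their targets up to pixel rounding.  Face noise is confined to
  grey values [10, 245] so the injected pixels alone determine UFR/OFR.

* :func:`make_study_table` emits face-pool records whose per-cohort quality
  score and comparison-outcome marginals default to the published study's
  cohort structure (four cohorts, 400 pools, 13 inconclusive).  The joint
  coupling of score and outcome inside a cohort is *not* published;
  deterministic mode pairs ascending scores with outcomes ordered
  correct-first, a synthetic choice documented as such.

* :func:`make_coupled_records` draws records with a caller-specified
  probability of an incorrect match per score level, so model-recovery
  tests can state their own truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .correctness_model import Cohort, FacePoolRecord, Outcome
from .exceptions import FixtureSpecError
from .imaging import FaceCropBox, GreyImage

__all__ = [
    "ImageSpec",
    "ImageGroundTruth",
    "CohortSpec",
    "DEFAULT_COHORTS",
    "make_image",
    "make_study_table",
    "make_coupled_records",
]

#: Grey band reserved for face noise so exposure injection stays exact.
_NOISE_LO, _NOISE_HI = 10, 245


@dataclass(frozen=True)
class ImageSpec:
    """Recipe for one synthetic face image.

    Defaults emulate the measured regime of the study corpus: face means
    around grey 70–90 (darker complexions), moderate spread, a brighter
    uniform background.
    """

    width: int
    height: int
    box: FaceCropBox
    face_mean: float = 85.0
    face_sd: float = 25.0
    ufr: float = 0.0
    ofr: float = 0.0
    background_grey: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise FixtureSpecError("image dimensions must be >= 1")
        if (
            self.box.left + self.box.width > self.width
            or self.box.top + self.box.height > self.height
        ):
            raise FixtureSpecError("face box must lie within the image")
        if not 0 <= self.ufr <= 1 or not 0 <= self.ofr <= 1:
            raise FixtureSpecError("exposure fractions must be in [0, 1]")
        if self.ufr + self.ofr > 1:
            raise FixtureSpecError(
                f"ufr + ofr = {self.ufr + self.ofr:.3f} exceeds 1: infeasible"
            )
        if not _NOISE_LO <= self.background_grey <= _NOISE_HI:
            raise FixtureSpecError(
                f"background grey must be in [{_NOISE_LO}, {_NOISE_HI}]"
            )
        if not _NOISE_LO <= self.face_mean <= _NOISE_HI:
            raise FixtureSpecError(
                f"face mean must be in [{_NOISE_LO}, {_NOISE_HI}]"
            )
        if self.face_sd <= 0:
            raise FixtureSpecError("face sd must be positive")


@dataclass(frozen=True)
class ImageGroundTruth:
    """Realized properties of a generated image, measured on the crop box."""

    fipp: float
    ufr: float
    ofr: float
    mean: float
    box: FaceCropBox
    n_dark: int
    n_bright: int


def make_image(spec: ImageSpec) -> Tuple[GreyImage, ImageGroundTruth]:
    """Generate one synthetic face image and its ground truth.

    Deterministic under ``spec.seed``: same spec → byte-identical raster.
    """
    rng = np.random.default_rng(spec.seed)
    canvas = np.full((spec.height, spec.width), spec.background_grey, dtype=np.int64)

    # Elliptical face inside the box, truncated-normal noise on [10, 245].
    box = spec.box
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cy, cx = box.top + (box.height - 1) / 2.0, box.left + (box.width - 1) / 2.0
    ry, rx = box.height / 2.0, box.width / 2.0
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    a = (_NOISE_LO - spec.face_mean) / spec.face_sd
    b = (_NOISE_HI - spec.face_mean) / spec.face_sd
    noise = stats.truncnorm.rvs(
        a, b, loc=spec.face_mean, scale=spec.face_sd,
        size=int(mask.sum()), random_state=rng,
    )
    canvas[mask] = np.clip(np.round(noise), _NOISE_LO, _NOISE_HI).astype(np.int64)

    # Inject exact counts of dark/bright pixels anywhere inside the box.
    area = box.area
    n_dark = int(round(spec.ufr * area))
    n_bright = int(round(spec.ofr * area))
    if n_dark + n_bright > area:
        raise FixtureSpecError("rounded exposure counts exceed the box area")
    box_rows = slice(box.top, box.top + box.height)
    box_cols = slice(box.left, box.left + box.width)
    flat = rng.choice(area, size=n_dark + n_bright, replace=False)
    sub = canvas[box_rows, box_cols].reshape(-1)
    sub[flat[:n_dark]] = rng.integers(0, 10, size=n_dark)
    sub[flat[n_dark:]] = rng.integers(246, 256, size=n_bright)
    canvas[box_rows, box_cols] = sub.reshape(box.height, box.width)

    image = GreyImage(canvas)
    crop_vals = canvas[box_rows, box_cols]
    truth = ImageGroundTruth(
        fipp=area / (spec.width * spec.height),
        ufr=n_dark / area,
        ofr=n_bright / area,
        mean=float(crop_vals.mean()),
        box=box,
        n_dark=n_dark,
        n_bright=n_bright,
    )
    return image, truth


@dataclass(frozen=True)
class CohortSpec:
    """Marginal structure of one capture cohort.

    ``score_counts`` is indexed by quality score 1–6; ``outcome_counts`` by
    (TP, TN, FP, FN, inconclusive).  Both must sum to the same cohort size.
    """

    cohort: Cohort
    score_counts: Tuple[int, int, int, int, int, int]
    outcome_counts: Tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.score_counts + self.outcome_counts):
            raise FixtureSpecError("counts must be non-negative")
        if sum(self.score_counts) != sum(self.outcome_counts):
            raise FixtureSpecError(
                f"{self.cohort.value}: score total {sum(self.score_counts)} "
                f"!= outcome total {sum(self.outcome_counts)}"
            )

    @property
    def size(self) -> int:
        return sum(self.score_counts)


#: Default cohort marginals: the published study's quality-score and
#: comparison-outcome distributions per cohort (400 pools in total).
DEFAULT_COHORTS: Tuple[CohortSpec, ...] = (
    CohortSpec(Cohort.WILDTYPE, (31, 34, 10, 0, 0, 0), (69, 5, 0, 1, 0)),
    CohortSpec(Cohort.STANDARD_CCTV, (0, 0, 15, 43, 17, 25), (71, 3, 21, 2, 3)),
    CohortSpec(Cohort.EYE_LEVEL_CCTV, (36, 38, 19, 2, 0, 0), (87, 5, 1, 2, 0)),
    CohortSpec(Cohort.ANALOGUE_CCTV, (0, 0, 0, 0, 0, 130), (27, 6, 2, 85, 10)),
)

_OUTCOME_ORDER = (
    Outcome.TRUE_POSITIVE,
    Outcome.TRUE_NEGATIVE,
    Outcome.FALSE_POSITIVE,
    Outcome.FALSE_NEGATIVE,
    Outcome.INCONCLUSIVE,
)


def make_study_table(
    cohorts: Sequence[CohortSpec] = DEFAULT_COHORTS,
    mode: str = "deterministic",
    seed: int = 0,
) -> List[FacePoolRecord]:
    """Face-pool records matching the per-cohort marginals exactly.

    ``deterministic`` mode pairs ascending quality scores with outcomes
    ordered correct-first (TP, TN, FP, FN, inconclusive) — a synthetic
    coupling in which poor scores line up with incorrect outcomes.
    ``sampled`` mode permutes the outcome list under ``seed``, preserving
    both marginals while randomizing the joint.
    """
    if mode not in ("deterministic", "sampled"):
        raise FixtureSpecError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    records: List[FacePoolRecord] = []
    for spec in cohorts:
        scores = [
            s for s, c in zip(range(1, 7), spec.score_counts) for _ in range(c)
        ]
        outcomes = [
            o for o, c in zip(_OUTCOME_ORDER, spec.outcome_counts) for _ in range(c)
        ]
        if mode == "sampled":
            outcomes = [outcomes[i] for i in rng.permutation(len(outcomes))]
        records.extend(
            FacePoolRecord(cohort=spec.cohort, quality_score=s, outcome=o)
            for s, o in zip(scores, outcomes)
        )
    return records


def make_coupled_records(
    n: int,
    p_incorrect_by_score: Mapping[int, float],
    score_weights: Optional[Mapping[int, float]] = None,
    cohort: Cohort = Cohort.STANDARD_CCTV,
    seed: int = 0,
) -> List[FacePoolRecord]:
    """Draw records with known P(incorrect | score) for recovery tests.

    Scores are drawn from ``score_weights`` (uniform over the keys of
    ``p_incorrect_by_score`` by default); the outcome is a Bernoulli draw
    mapped to TP (correct) or FN (incorrect).
    """
    if n < 1:
        raise FixtureSpecError("n must be >= 1")
    levels = sorted(p_incorrect_by_score)
    if not levels:
        raise FixtureSpecError("p_incorrect_by_score must not be empty")
    for s, p in p_incorrect_by_score.items():
        if not 1 <= s <= 6:
            raise FixtureSpecError(f"score {s} outside 1-6")
        if not 0 <= p <= 1:
            raise FixtureSpecError(f"probability {p} outside [0, 1]")
    if score_weights is None:
        w = np.full(len(levels), 1.0 / len(levels))
    else:
        w = np.array([float(score_weights[s]) for s in levels])
        if (w < 0).any() or w.sum() <= 0:
            raise FixtureSpecError("score weights must be non-negative, sum > 0")
        w = w / w.sum()
    rng = np.random.default_rng(seed)
    scores = rng.choice(levels, size=n, p=w)
    p_inc = np.array([p_incorrect_by_score[s] for s in scores])
    incorrect = rng.random(n) < p_inc
    return [
        FacePoolRecord(
            cohort=cohort,
            quality_score=int(s),
            outcome=Outcome.FALSE_NEGATIVE if bad else Outcome.TRUE_POSITIVE,
        )
        for s, bad in zip(scores, incorrect)
    ]
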