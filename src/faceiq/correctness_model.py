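"""Predicting match correctness from quality scores.

Each face pool (one target image compared against ten candidates) ends in a
comparison outcome: true positive, true negative, false positive, false
negative, or inconclusive.  Outcomes collapse to a binary *match
correctness* — TP/TN are correct, FP/FN incorrect, inconclusive pools are
excluded from modelling.

An L2-penalized logistic regression predicts incorrectness from the ordinal
quality score entered as one-hot indicators with score 1 as the reference
level (the intercept).  Positive coefficients therefore mean a higher
probability of an incorrect match.  The penalty strength λ (objective
−loglik + λ‖β‖²/2) is tuned over a log-spaced grid by cross-validated
accuracy on the training split; classification uses a 0.5 probability
threshold; evaluation tabulates a confusion matrix with *correct* as the
positive class, from which accuracy, precision (TP/(TP+FP)) and recall
(TP/(TP+FN)) follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .exceptions import DegenerateFitError, InvalidInputError

__all__ = [
    "Cohort",
    "Outcome",
    "Correctness",
    "FacePoolRecord",
    "ConfusionCounts",
    "ModelFit",
    "split",
    "fit",
    "predict_incorrect_probability",
    "evaluate",
    "metrics",
    "DEFAULT_PENALTY_GRID",
]


class Cohort(str, Enum):
    WILDTYPE = "wildtype"
    STANDARD_CCTV = "standard_cctv"
    EYE_LEVEL_CCTV = "eye_level_cctv"
    ANALOGUE_CCTV = "analogue_cctv"


class Outcome(str, Enum):
    TRUE_POSITIVE = "true_positive"
    TRUE_NEGATIVE = "true_negative"
    FALSE_POSITIVE = "false_positive"
    FALSE_NEGATIVE = "false_negative"
    INCONCLUSIVE = "inconclusive"


class Correctness(str, Enum):
    CORRECT = "correct"
    INCORRECT = "incorrect"
    EXCLUDED = "excluded"


_CORRECTNESS = {
    Outcome.TRUE_POSITIVE: Correctness.CORRECT,
    Outcome.TRUE_NEGATIVE: Correctness.CORRECT,
    Outcome.FALSE_POSITIVE: Correctness.INCORRECT,
    Outcome.FALSE_NEGATIVE: Correctness.INCORRECT,
    Outcome.INCONCLUSIVE: Correctness.EXCLUDED,
}


@dataclass(frozen=True)
class FacePoolRecord:
    """One face pool: capture cohort, quality score and comparison outcome."""

    cohort: Cohort
    quality_score: int
    outcome: Outcome

    def __post_init__(self) -> None:
        if not 1 <= self.quality_score <= 6:
            raise InvalidInputError(
                f"quality score must be 1-6, got {self.quality_score}"
            )

    @property
    def correctness(self) -> Correctness:
        return _CORRECTNESS[self.outcome]


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion matrix with the *correct* match as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")
        if self.total < 1:
            raise InvalidInputError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ModelFit:
    """Fitted penalized logistic model over one-hot score indicators.

    ``intercept`` is the log-odds of an incorrect match at the reference
    level (score 1, or the lowest score present); ``coefficients`` maps each
    other score level to its log-odds offset.
    """

    intercept: float
    coefficients: Dict[int, float]
    penalty: float
    reference_level: int
    split_seed: Optional[int] = None
    cv_accuracy: Optional[float] = None

    @property
    def levels(self) -> Tuple[int, ...]:
        return (self.reference_level, *sorted(self.coefficients))


#: λ grid spanning effectively-unpenalized (1e-10) to strongly shrunk (1e2).
DEFAULT_PENALTY_GRID: Tuple[float, ...] = tuple(
    float(10.0**e) for e in range(-10, 3)
)


def analysed(records: Sequence[FacePoolRecord]) -> List[FacePoolRecord]:
    """Records entering correctness analyses (inconclusive pools dropped)."""
    return [r for r in records if r.correctness is not Correctness.EXCLUDED]


def split(
    records: Sequence[FacePoolRecord],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> Tuple[List[FacePoolRecord], List[FacePoolRecord]]:
    """Random unstratified train/test partition of the analysable records.

    Inconclusive records are dropped first; the remaining n records are
    permuted uniformly under ``seed`` and the first ``floor(fraction * n)``
    form the training set.  The partition is exact: no overlap, full
    coverage of the analysable records.
    """
    if not 0 < train_fraction < 1:
        raise InvalidInputError(
            f"train_fraction must be in (0, 1), got {train_fraction}"
        )
    usable = analysed(records)
    if len(usable) < 2:
        raise DegenerateFitError(
            "need at least 2 non-excluded records to split; "
            f"got {len(usable)} of {len(records)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(usable))
    n_train = int(np.floor(train_fraction * len(usable)))
    train = [usable[i] for i in order[:n_train]]
    test = [usable[i] for i in order[n_train:]]
    return train, test


def _design(
    records: Sequence[FacePoolRecord], levels: Sequence[int], reference: int
) -> np.ndarray:
    cols = [lv for lv in levels if lv != reference]
    X = np.zeros((len(records), len(cols)))
    for i, r in enumerate(records):
        if r.quality_score in cols:
            X[i, cols.index(r.quality_score)] = 1.0
    return X


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, penalty: float, n_folds: int
) -> float:
    cv = StratifiedKFold(n_splits=n_folds, shuffle=False)
    accs = []
    for train_idx, test_idx in cv.split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            continue
        model = _sklearn_fit(X[train_idx], y[train_idx], penalty)
        pred = model.predict(X[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
    if not accs:
        raise DegenerateFitError("cross-validation folds were single-class")
    return float(np.mean(accs))


def _sklearn_fit(X: np.ndarray, y: np.ndarray, penalty: float) -> LogisticRegression:
    # sklearn minimizes ||w||^2 / (2C) + sum loglik terms (L2 default),
    # so C = 1/λ.
    C = 1.0 / penalty if penalty > 0 else 1e12
    model = LogisticRegression(C=C, solver="lbfgs", tol=1e-10, max_iter=20_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def fit(
    train: Sequence[FacePoolRecord],
    penalty_grid: Optional[Sequence[float]] = None,
    cv_folds: int = 5,
    split_seed: Optional[int] = None,
) -> ModelFit:
    """Fit the penalized logistic correctness model on training records.

    The penalty is selected from ``penalty_grid`` by mean cross-validated
    accuracy (deterministic unshuffled stratified folds); ties resolve to
    the smallest penalty.  Excluded (inconclusive) records are rejected.
    """
    grid = sorted(set(penalty_grid if penalty_grid is not None else DEFAULT_PENALTY_GRID))
    if any(p < 0 for p in grid):
        raise InvalidInputError("penalties must be non-negative")
    usable = list(train)
    if any(r.correctness is Correctness.EXCLUDED for r in usable):
        raise InvalidInputError("inconclusive records must not enter model fitting")
    y = np.array(
        [1.0 if r.correctness is Correctness.INCORRECT else 0.0 for r in usable]
    )
    if len(np.unique(y)) < 2:
        raise DegenerateFitError(
            "training data contain a single correctness class; cannot fit"
        )
    levels = sorted({r.quality_score for r in usable})
    reference = levels[0]
    X = _design(usable, levels, reference)

    cv_acc: Optional[float] = None
    if len(grid) == 1:
        best = grid[0]
    else:
        n_folds = min(cv_folds, int(np.bincount(y.astype(int)).min()))
        if n_folds < 2:
            best = grid[0]
        else:
            scores = [(_cv_accuracy(X, y, p, n_folds), p) for p in grid]
            cv_acc = max(s for s, _ in scores)
            best = min(p for s, p in scores if s == cv_acc)

    model = _sklearn_fit(X, y, best)
    cols = [lv for lv in levels if lv != reference]
    return ModelFit(
        intercept=float(model.intercept_[0]),
        coefficients={lv: float(b) for lv, b in zip(cols, model.coef_[0])},
        penalty=float(best),
        reference_level=reference,
        split_seed=split_seed,
        cv_accuracy=cv_acc,
    )


def predict_incorrect_probability(
    model: ModelFit, quality_scores: Sequence[int]
) -> np.ndarray:
    """P(incorrect match) per score; unseen levels fall back to the reference."""
    unseen = sorted(
        {s for s in quality_scores if s not in model.levels}
    )
    if unseen:
        warnings.warn(
            f"score level(s) {unseen} unseen in training; treated as the "
            f"reference level {model.reference_level}",
            stacklevel=2,
        )
    logit = np.array(
        [
            model.intercept + model.coefficients.get(s, 0.0)
            for s in quality_scores
        ]
    )
    return 1.0 / (1.0 + np.exp(-logit))


def evaluate(
    model: ModelFit,
    test: Sequence[FacePoolRecord],
    threshold: float = 0.5,
) -> ConfusionCounts:
    """Confusion matrix of the model on a test set (correct = positive)."""
    if not test:
        raise InvalidInputError("test set is empty")
    usable = analysed(test)
    p_inc = predict_incorrect_probability(
        model, [r.quality_score for r in usable]
    )
    pred_correct = p_inc < threshold
    actual_correct = np.array(
        [r.correctness is Correctness.CORRECT for r in usable]
    )
    return ConfusionCounts(
        tp=int(np.sum(pred_correct & actual_correct)),
        fp=int(np.sum(pred_correct & ~actual_correct)),
        fn=int(np.sum(~pred_correct & actual_correct)),
        tn=int(np.sum(~pred_correct & ~actual_correct)),
    )


def metrics(c: ConfusionCounts) -> Dict[str, Optional[float]]:
    """Accuracy, precision (TP/(TP+FP)) and recall (TP/(TP+FN)).

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never as 0.
    """
    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "precision": c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else None,
        "recall": c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else None,
    }
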