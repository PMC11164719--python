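"""256-bin greyscale histograms and face-exposure statistics.

Per cropped face image the pipeline records the full 256-bin histogram and a
summary block: mean, median, mode, standard deviation, skewness, minimum and
maximum grey value, plus two exposure ratios —

* **UFR** (underexposed face ratio): pixels in the 10 darkest bins
  (grey values 0–9) divided by the total pixel count;
* **OFR** (overexposed face ratio): pixels in the 10 brightest bins
  (grey values 246–255) divided by the total pixel count.

Moments are *population* moments (the convention of histogram-based image
tools); mode and median ties resolve to the smallest qualifying grey value.
Batch extraction mirrors the folder-walking macro workflow, emitting one CSV
of raw bin counts and one of summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .imaging import GreyImage, load_grey

__all__ = [
    "GreyHistogram",
    "ExposureSummary",
    "BatchResult",
    "histogram",
    "underexposed_ratio",
    "overexposed_ratio",
    "summarize",
    "batch_extract",
    "IMAGE_EXTENSIONS",
]

logger = logging.getLogger(__name__)

#: Grey values counted as under-/over-exposed (first and last 10 bins).
DARK_BINS = range(0, 10)
BRIGHT_BINS = range(246, 256)

IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


@dataclass(frozen=True, eq=False)
class GreyHistogram:
    """Counts of pixels at each of the 256 grey values."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (256,):
            raise InvalidInputError(f"histogram needs 256 bins, got shape {arr.shape}")
        if (arr < 0).any():
            raise InvalidInputError("histogram counts must be non-negative")
        if arr.sum() < 1:
            raise InvalidInputError("histogram must contain at least one pixel")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GreyHistogram):
            return NotImplemented
        return bool(np.array_equal(self.counts, other.counts))


@dataclass(frozen=True)
class ExposureSummary:
    """Summary statistics of one face histogram.

    ``degenerate`` is set when every pixel shares one grey value, in which
    case the skewness is reported as 0 rather than 0/0.
    """

    total: int
    ufr: float
    ofr: float
    mean: float
    median: int
    mode: int
    sd: float
    skewness: float
    min: int
    max: int
    degenerate: bool = False


def histogram(image: GreyImage) -> GreyHistogram:
    """Tally pixels of ``image`` into the 256 grey-value bins."""
    counts = np.bincount(image.values.ravel(), minlength=256)
    return GreyHistogram(counts)


def underexposed_ratio(h: GreyHistogram) -> float:
    """Fraction of pixels in the 10 darkest bins (grey values 0-9)."""
    return int(h.counts[DARK_BINS.start : DARK_BINS.stop].sum()) / h.total


def overexposed_ratio(h: GreyHistogram) -> float:
    """Fraction of pixels in the 10 brightest bins (grey values 246-255)."""
    return int(h.counts[BRIGHT_BINS.start : BRIGHT_BINS.stop].sum()) / h.total


def summarize(h: GreyHistogram) -> ExposureSummary:
    """Exposure summary of a histogram using population moments.

    mean = Σ v·c_v / N; sd = sqrt(m2); skewness = m3 / m2^(3/2) with m2, m3
    the population central moments.  The median is the smallest grey value
    whose cumulative count reaches ceil(N/2); the mode is the smallest grey
    value attaining the maximum count.
    """
    counts = h.counts
    total = h.total
    values = np.arange(256, dtype=np.float64)

    mean = float((values * counts).sum() / total)
    dev = values - mean
    m2 = float((dev**2 * counts).sum() / total)
    m3 = float((dev**3 * counts).sum() / total)
    sd = math.sqrt(m2)
    degenerate = m2 == 0.0
    skewness = 0.0 if degenerate else m3 / m2**1.5

    cum = np.cumsum(counts)
    median = int(np.searchsorted(cum, math.ceil(total / 2)))
    mode = int(np.argmax(counts))
    occupied = np.nonzero(counts)[0]
    return ExposureSummary(
        total=total,
        ufr=underexposed_ratio(h),
        ofr=overexposed_ratio(h),
        mean=mean,
        median=median,
        mode=mode,
        sd=sd,
        skewness=skewness,
        min=int(occupied[0]),
        max=int(occupied[-1]),
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class BatchResult:
    """Outcome of a folder extraction: processed filenames and failures."""

    processed: tuple
    skipped: tuple

    @property
    def ok(self) -> bool:
        return not self.skipped


def _summary_row(name: str, s: ExposureSummary) -> dict:
    return {
        "file": name,
        "total": s.total,
        "mean": s.mean,
        "median": s.median,
        "mode": s.mode,
        "sd": s.sd,
        "skewness": s.skewness,
        "min": s.min,
        "max": s.max,
        "ufr": s.ufr,
        "ofr": s.ofr,
    }


def batch_extract(
    folder: Union[str, Path],
    histograms_csv: Union[str, Path],
    summaries_csv: Union[str, Path],
    conversion: str = "unweighted",
    extensions: Optional[Sequence[str]] = None,
) -> BatchResult:
    """Histogram every image in ``folder`` and write two CSV files.

    ``histograms_csv`` holds one row per image with the raw bin counts
    (``file,total,c0..c255``); ``summaries_csv`` holds the summary statistics
    plus UFR/OFR (``file,total,mean,median,mode,sd,skewness,min,max,ufr,ofr``).
    Files are processed in lexicographic filename order.  Unreadable files
    are logged and skipped; the returned :class:`BatchResult` records them so
    callers can signal a nonzero exit.
    """
    folder = Path(folder)
    exts = set(extensions) if extensions is not None else IMAGE_EXTENSIONS
    if not folder.is_dir():
        raise InvalidInputError(f"not a directory: {folder}")
    paths = sorted(
        (p for p in folder.iterdir() if p.suffix.lower() in exts),
        key=lambda p: p.name,
    )
    if not paths:
        raise InvalidInputError(f"no images found in {folder}")

    hist_rows, summary_rows, processed, skipped = [], [], [], []
    for path in paths:
        try:
            image = load_grey(path, conversion=conversion)
        except Exception as exc:  # decode errors must not abort the batch
            logger.warning("skipping %s: %s", path.name, exc)
            skipped.append(path.name)
            continue
        h = histogram(image)
        row = {"file": path.name, "total": h.total}
        row.update({f"c{v}": int(h.counts[v]) for v in range(256)})
        hist_rows.append(row)
        summary_rows.append(_summary_row(path.name, summarize(h)))
        processed.append(path.name)

    if not hist_rows:
        raise InvalidInputError(f"no readable images in {folder}")
    pd.DataFrame(hist_rows).to_csv(histograms_csv, index=False)
    pd.DataFrame(summary_rows).to_csv(summaries_csv, index=False)
    return BatchResult(processed=tuple(processed), skipped=tuple(skipped))
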