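"""Multi-reader ageing precision: consensus ages, readability filtering,
IAPE and CV.

Ages are estimated by counting vertebral band pairs; each animal is read
blind by several readers.  Precision between readers is summarised by the
index of average percent error (IAPE, Beamish-Fournier) and the percent
coefficient of variation (CV, Chang):

    APE_j  = (100 / R) * sum_i |x_ij - xbar_j| / xbar_j
    IAPE   = mean_j APE_j
    CV_j   = 100 * sd_j / xbar_j          (sample sd, R - 1 denominator)
    CV     = mean_j CV_j

where x_ij is reader i's age for animal j and xbar_j the animal's mean age.
On two-reader data CV_j = sqrt(2) * APE_j exactly.  Per-reader variants
average each reader's own scaled deviation from the animal mean across
animals (an interpretation; the classical indices are the overall ones).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .models import SizeAtAgeRecord

__all__ = [
    "ReaderMatrix",
    "consensus_age",
    "filter_readability",
    "iape",
    "cv_index",
    "PrecisionError",
]

UNRESOLVED = "unresolved"


class PrecisionError(ValueError):
    pass


@dataclass
class ReaderMatrix:
    """Animals x readers table of band-pair age reads."""

    animal_ids: Sequence
    reads: np.ndarray  # shape (n_animals, n_readers)
    readability: Optional[np.ndarray] = None  # per-animal 1..3

    def __post_init__(self) -> None:
        self.reads = np.asarray(self.reads, dtype=float)
        if self.reads.ndim != 2 or self.reads.shape[1] < 2:
            raise PrecisionError("reads must be animals x readers with >= 2 readers")
        if len(self.animal_ids) != self.reads.shape[0]:
            raise PrecisionError("animal_ids length must match reads rows")
        if np.any(~np.isfinite(self.reads)) or np.any(self.reads < 0):
            raise PrecisionError("all reads must be finite and >= 0")
        if self.readability is not None:
            self.readability = np.asarray(self.readability, dtype=int)
            if len(self.readability) != self.reads.shape[0]:
                raise PrecisionError("readability length must match reads rows")
            bad = set(np.unique(self.readability)) - {1, 2, 3}
            if bad:
                raise PrecisionError(f"readability scores outside {{1,2,3}}: {sorted(bad)}")

    @property
    def n_readers(self) -> int:
        return self.reads.shape[1]


def consensus_age(reads: Sequence[float]) -> Union[float, str]:
    """Final age when two or more readers agree; ``"unresolved"`` otherwise.

    With four or more readers a tie between two equally frequent modal
    values is also unresolved.
    """
    reads = [float(r) for r in reads]
    if len(reads) < 2:
        raise PrecisionError("need at least 2 reads")
    vals, counts = np.unique(reads, return_counts=True)
    top = counts.max()
    if top < 2:
        return UNRESOLVED
    winners = vals[counts == top]
    if len(winners) > 1:
        return UNRESOLVED
    return float(winners[0])


def filter_readability(
    records: Sequence[SizeAtAgeRecord],
    matrix: Optional[ReaderMatrix] = None,
):
    """Drop readability-3 animals; report counts per score class.

    Returns ``(retained_records, retained_matrix_or_None, report)`` where
    ``report`` maps each observed score to its count.  Records lacking a
    readability score pass through untouched (and are not counted).
    """
    scores = [r.readability for r in records]
    report: dict[int, int] = {}
    keep = []
    for idx, (rec, s) in enumerate(zip(records, scores)):
        if s is not None:
            if s not in (1, 2, 3):
                raise PrecisionError(f"readability score {s} outside {{1,2,3}}")
            report[s] = report.get(s, 0) + 1
        if s != 3:
            keep.append(idx)
    retained = [records[i] for i in keep]
    sub_matrix = None
    if matrix is not None:
        sub_matrix = ReaderMatrix(
            animal_ids=[matrix.animal_ids[i] for i in keep],
            reads=matrix.reads[keep],
            readability=None if matrix.readability is None else matrix.readability[keep],
        )
    return retained, sub_matrix, report


def _check_means(matrix: ReaderMatrix) -> np.ndarray:
    means = matrix.reads.mean(axis=1)
    zero = np.where(means <= 0)[0]
    if len(zero):
        raise PrecisionError(
            f"animal(s) with mean age 0 (undefined percent error): "
            f"{[matrix.animal_ids[i] for i in zero]}"
        )
    return means


def iape(matrix: ReaderMatrix, per_reader: bool = False):
    """Index of average percent error, %, over all animals.

    With ``per_reader`` also returns each reader's mean percent absolute
    deviation from the per-animal mean.
    """
    means = _check_means(matrix)
    dev = 100.0 * np.abs(matrix.reads - means[:, None]) / means[:, None]
    overall = float(dev.mean(axis=1).mean())
    if per_reader:
        return overall, dev.mean(axis=0)
    return overall


def cv_index(matrix: ReaderMatrix, per_reader: bool = False):
    """Mean percent coefficient of variation of reads across animals.

    The per-reader variant scales each reader's absolute deviation by
    sqrt(R / (R - 1)) so that its across-reader average matches the
    per-animal CV's use of the sample standard deviation.
    """
    means = _check_means(matrix)
    sd = matrix.reads.std(axis=1, ddof=1)
    overall = float((100.0 * sd / means).mean())
    if per_reader:
        r = matrix.n_readers
        dev = (
            100.0
            * np.abs(matrix.reads - means[:, None])
            / means[:, None]
            * np.sqrt(r / (r - 1.0))
        )
        return overall, dev.mean(axis=0)
    return overall
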