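"""Correlation of per-feature weights across analyses.

Used for two comparisons: left-eye vs right-eye image features within
the awareness decode (a positive correlation is expected — the two eyes
saw draws from the same stimulus population), and side-averaged
awareness weights vs expression-decoding weights (the substantive
question: is first-percept prediction driven by expression-defining
features?).  Features never tested by any model carry weight exactly 0
and are excluded pairwise by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
from scipy import stats

from .exceptions import DataError, UndefinedCorrelationError

__all__ = ["CorrelationResult", "split_sides", "average_sides", "correlate_weights"]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r, its two-tailed p (t transform, n-2 df), and the pair count."""

    r: float
    p: float
    n: int

    def __post_init__(self):
        if abs(self.r) > 1 + 1e-12:
            raise DataError("|r| must be <= 1")
        if self.n < 3:
            raise DataError("a defined p needs n >= 3 pairs")


def _weights_vector(relevance) -> np.ndarray:
    """Accept a raw vector, a relevance-record list, or a relevance frame."""
    if hasattr(relevance, "columns"):  # DataFrame from EnsembleResult
        return relevance.sort_values("feature_id")["weight"].to_numpy(dtype=float)
    rel = list(relevance) if isinstance(relevance, Iterable) else relevance
    if rel and hasattr(rel[0], "weight"):
        return np.array([r.weight for r in sorted(rel, key=lambda r: r.feature_id)])
    return np.asarray(rel, dtype=float)


def split_sides(relevance) -> tuple[np.ndarray, np.ndarray]:
    """Split 2k weights into the left-image half and the right-image half.

    Positions 0..k-1 of a trial feature row belong to the left image and
    k..2k-1 to the right image, in identical wedge order.
    """
    w = _weights_vector(relevance)
    if w.size == 0 or w.size % 2:
        raise DataError(f"need an even number of weights; got {w.size}")
    half = w.size // 2
    return w[:half].copy(), w[half:].copy()


def average_sides(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Element-wise mean of the two sides' weights (wedge order preserved)."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise DataError("left/right weight vectors must have equal length")
    return (left + right) / 2.0


def correlate_weights(
    a,
    b,
    exclusion: Union[str, set, frozenset, None] = "untested_either",
) -> CorrelationResult:
    """Pearson correlation of two weight vectors with untested-feature exclusion.

    ``exclusion``:

    * ``"untested_either"`` (default) — drop pairs where either weight is
      exactly 0 (the marker of a never-tested feature);
    * ``"none"`` — keep all pairs;
    * a set of feature ids — restrict to that subset (e.g. the features
      significant for expression decoding).
    """
    a = _weights_vector(a)
    b = _weights_vector(b)
    if a.shape != b.shape:
        raise DataError("weight vectors must have equal length")

    if isinstance(exclusion, (set, frozenset)):
        idx = np.array(sorted(exclusion), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= a.size):
            raise DataError("subset contains feature ids outside the vector")
        mask = np.zeros(a.size, dtype=bool)
        mask[idx] = True
    elif exclusion in ("untested_either", None):
        mask = (a != 0) & (b != 0)
    elif exclusion == "none":
        mask = np.ones(a.size, dtype=bool)
    else:
        raise DataError(f"unknown exclusion mode {exclusion!r}")

    x, y = a[mask], b[mask]
    n = int(x.size)
    if n < 3:
        raise DataError(f"only {n} pairs retained; need >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("a retained weight vector has zero variance")

    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)
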