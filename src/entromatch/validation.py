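"""Model-vs-test comparison statistics.

A built model and a held-out test campaign each produce, per entropy
class, a vector of quartile shares (one cell per algorithm x quartile).
Agreement is summarized three ways:

* the double-scaled Euclidean distance d2 = sqrt(sum_i (p1_i - p2_i)^2
  / md_i) / sqrt(v), where md_i is the maximum possible squared
  discrepancy of variable i (1 for shares bounded by 0 and 1) and v the
  number of compared variables -- d2 lies in [0, 1];
* the similarity coefficient 1 - d2;
* the Pearson product-moment correlation between the two share vectors.

Variables entering the comparison are the (algorithm, quartile) cells
with a nonzero entry in either vector, in fixed (alphabetical algorithm,
quartile) order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .model_pipeline import QuartileShares, RankingModel

__all__ = [
    "AlignedShares",
    "ValidationReport",
    "scaled_discrepancy",
    "double_scaled_euclidean",
    "pearson_correlation",
    "distribution_summary",
    "align_class_shares",
    "compare_class",
    "validate_model",
]


@dataclass(frozen=True)
class AlignedShares:
    """Paired model/test share vectors with per-variable maximum discrepancy."""

    p1: Tuple[float, ...]
    p2: Tuple[float, ...]
    md: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.p1) == len(self.p2) == len(self.md)):
            raise ValueError("p1, p2 and md must have equal length")
        if len(self.p1) < 1:
            raise ValueError("need at least one variable")
        if any(m <= 0 for m in self.md):
            raise ValueError("every md_i must be positive")

    @property
    def v(self) -> int:
        return len(self.p1)


def scaled_discrepancy(p1_i: float, p2_i: float, md_i: float = 1.0) -> float:
    """One variable's squared discrepancy scaled by its maximum, (p1-p2)^2/md."""
    if md_i <= 0:
        raise ValueError("md_i must be positive")
    return (p1_i - p2_i) ** 2 / md_i


@dataclass(frozen=True)
class ValidationReport:
    """Distance, similarity and correlation between two share vectors."""

    d2: float
    similarity: float
    pearson_r: Optional[float]
    v: int


def double_scaled_euclidean(shares: AlignedShares) -> ValidationReport:
    """Double-scaled Euclidean distance and the derived similarity.

    ``d2 = sqrt(sum_i (p1_i - p2_i)^2 / md_i) / sqrt(v)``;
    ``similarity = 1 - d2``.  With md_i = 1 this is the root-mean-square
    share difference, 0 for identical vectors and 1 at maximum
    discrepancy.
    """
    total = sum(
        scaled_discrepancy(a, b, m) for a, b, m in zip(shares.p1, shares.p2, shares.md)
    )
    d2 = math.sqrt(total) / math.sqrt(shares.v)
    r = pearson_correlation(shares.p1, shares.p2) if shares.v >= 2 else None
    return ValidationReport(d2=d2, similarity=1.0 - d2, pearson_r=r, v=shares.v)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Product-moment correlation; None when undefined (constant input)."""
    if len(x) != len(y):
        raise ValueError("sequences must have equal length")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = stats.pearsonr(xa, ya).statistic
    return float(r)


def distribution_summary(
    entropies: Sequence[float], bins: int = 10
) -> Tuple[float, float, np.ndarray]:
    """Sample mean, sample standard deviation (n-1) and histogram counts."""
    arr = np.asarray(entropies, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    counts, _ = np.histogram(arr, bins=bins)
    return float(np.mean(arr)), sd, counts


# ---------------------------------------------------------------------------
# share-vector alignment between a model and test results

_SharesLike = Union[QuartileShares, RankingModel]


def _class_cells(
    shares: _SharesLike, class_index: int
) -> Mapping[str, Tuple[float, float, float, float]]:
    qs = shares.shares if isinstance(shares, RankingModel) else shares
    return qs.shares[class_index]


def align_class_shares(
    model_shares: _SharesLike,
    test_shares: _SharesLike,
    class_index: int,
    md: float = 1.0,
) -> Optional[AlignedShares]:
    """Pair up one class's (algorithm, quartile) cells from two campaigns.

    Cells that are zero in both vectors carry no information and are
    dropped; the rest keep a fixed (alphabetical algorithm, quartile)
    order.  Returns None when every cell is zero on both sides (an empty
    class in both campaigns).
    """
    m_cells = _class_cells(model_shares, class_index)
    t_cells = _class_cells(test_shares, class_index)
    algorithms = sorted(set(m_cells) & set(t_cells))
    if not algorithms:
        raise ValueError("no common algorithms between model and test shares")
    p1: List[float] = []
    p2: List[float] = []
    for a in algorithms:
        for q in range(4):
            x, y = m_cells[a][q], t_cells[a][q]
            if x != 0.0 or y != 0.0:
                p1.append(x)
                p2.append(y)
    if not p1:
        return None
    return AlignedShares(p1=tuple(p1), p2=tuple(p2), md=(md,) * len(p1))


def compare_class(
    model_shares: _SharesLike,
    test_shares: _SharesLike,
    class_index: int,
    md: float = 1.0,
) -> ValidationReport:
    """Validation statistics for one entropy class.

    A class empty in both campaigns is reported as perfectly similar
    (d2 = 0) with undefined correlation.
    """
    aligned = align_class_shares(model_shares, test_shares, class_index, md=md)
    if aligned is None:
        return ValidationReport(d2=0.0, similarity=1.0, pearson_r=None, v=0)
    return double_scaled_euclidean(aligned)


def validate_model(
    model: RankingModel,
    test_shares: _SharesLike,
    classes: Optional[Sequence[int]] = None,
    md: float = 1.0,
) -> Dict[int, ValidationReport]:
    """Per-class validation reports for a model against held-out shares."""
    if classes is None:
        classes = range(1, model.scheme.class_count + 1)
    return {k: compare_class(model, test_shares, k, md=md) for k in classes}
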