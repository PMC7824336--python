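"""Pattern entropy, sample sizing and frequency-distribution discretization.

Patterns are characterized by the Shannon entropy of their character
frequencies, H = -sum_c p_c log2 p_c (bits), with every character --
including spaces, punctuation and case variants -- treated as a distinct
symbol.  Rounded (2-decimal) entropies are discretized into C classes of
equal width by the frequency-distribution rule C = round(2 * n^(1/3)),
where n is the number of distinct rounded values observed; class
boundaries tile [min, max].

The sample-size helper implements the finite-population correction
n' = n0 / (1 + n0/N) with n0 = z^2 p (1-p) / eps^2, the standard survey
formula for how many patterns a campaign needs so that observed
proportions are within +-eps of the population value at the chosen
confidence level.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence, Tuple

__all__ = [
    "EntropyResult",
    "SampleSpec",
    "ClassScheme",
    "shannon_entropy",
    "round_entropy",
    "sample_size",
    "num_classes",
    "build_class_scheme",
    "assign_class",
]


def shannon_entropy(pattern: str) -> float:
    """Base-2 Shannon entropy of a pattern's character frequencies, in bits.

    Zero iff the pattern repeats a single character; at most
    log2(min(len(pattern), alphabet size)).
    """
    if not isinstance(pattern, str):
        raise TypeError("pattern must be a string")
    m = len(pattern)
    if m == 0:
        raise ValueError("pattern must have length >= 1")
    h = -sum((c / m) * math.log2(c / m) for c in Counter(pattern).values())
    return h if h else 0.0  # normalize -0.0 from the single-symbol case


def round_entropy(h: float) -> float:
    """Round an entropy to 2 decimals, halves away from zero."""
    if h < 0:
        raise ValueError("entropy must be nonnegative")
    return float(Decimal(repr(h)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EntropyResult:
    """A pattern with its exact and 2-decimal-rounded entropy."""

    pattern: str
    patt_ent: float
    patt_ent_round: float

    @classmethod
    def from_pattern(cls, pattern: str) -> "EntropyResult":
        h = shannon_entropy(pattern)
        return cls(pattern=pattern, patt_ent=h, patt_ent_round=round_entropy(h))


def sample_size(
    population_size: int,
    z_score: float = 1.96,
    margin: float = 0.01,
    proportion: float = 0.5,
) -> int:
    """Finite-population sample size, rounded up to whole patterns.

    ``ceil(n0 / (1 + n0/N))`` with ``n0 = z^2 p (1-p) / margin^2``.  As the
    population grows the result is nondecreasing and converges to
    ``ceil(n0)``.  Defaults correspond to 95% confidence (z=1.96) with a
    +-1% margin and the conservative p=0.5.
    """
    if population_size < 1:
        raise ValueError("population_size must be >= 1")
    if not 0 < margin < 1:
        raise ValueError("margin must lie in (0, 1)")
    if not 0 < proportion < 1:
        raise ValueError("proportion must lie in (0, 1)")
    if z_score <= 0:
        raise ValueError("z_score must be positive")
    n0 = z_score**2 * proportion * (1 - proportion) / margin**2
    return math.ceil(n0 / (1 + n0 / population_size))


@dataclass(frozen=True)
class SampleSpec:
    """A campaign sizing: population, survey parameters, required sample."""

    population_size: int
    z_score: float
    margin: float
    proportion: float
    required_n: int

    @classmethod
    def compute(
        cls,
        population_size: int,
        z_score: float = 1.96,
        margin: float = 0.01,
        proportion: float = 0.5,
    ) -> "SampleSpec":
        return cls(
            population_size=population_size,
            z_score=z_score,
            margin=margin,
            proportion=proportion,
            required_n=sample_size(population_size, z_score, margin, proportion),
        )


def num_classes(n_observations: int) -> int:
    """Class count C = round(2 * n^(1/3)), half away from zero, minimum 1."""
    if n_observations < 1:
        raise ValueError("n_observations must be >= 1")
    c = 2.0 * n_observations ** (1.0 / 3.0)
    return max(1, int(Decimal(repr(c)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)))


@dataclass(frozen=True)
class ClassScheme:
    """Equal-width discretization of rounded entropies into C classes.

    ``boundaries`` holds the C-1 interior cut points b_k = minimum + k*width;
    class k (1-based) covers [b_{k-1}, b_k), the first class is open below
    and the last class is unbounded above ("%s" labels mirror that:
    ``<b1``, ``b1-b2``, ..., ``>=b_{C-1}``).
    """

    class_count: int
    width: float
    minimum: float
    maximum: float
    boundaries: Tuple[float, ...]
    labels: Tuple[str, ...]


def _format_bound(x: float) -> str:
    return f"{x:.5f}"


def build_class_scheme(rounded_entropies: Sequence[float]) -> ClassScheme:
    """Discretize observed rounded entropies into equal-width classes.

    The class count comes from :func:`num_classes` applied to the number of
    *distinct* values; the width is (max - min) / C.  If every value is
    identical the scheme degenerates to a single class of width 0.
    """
    values = sorted(set(float(v) for v in rounded_entropies))
    if not values:
        raise ValueError("need at least one entropy value")
    if any(v < 0 for v in values):
        raise ValueError("entropies must be nonnegative")
    lo, hi = values[0], values[-1]
    if lo == hi:
        return ClassScheme(
            class_count=1,
            width=0.0,
            minimum=lo,
            maximum=hi,
            boundaries=(),
            labels=(f"≥{_format_bound(lo)}",),
        )
    c = num_classes(len(values))
    width = (hi - lo) / c
    boundaries = tuple(lo + k * width for k in range(1, c))
    labels = []
    for k in range(1, c + 1):
        if k == 1:
            labels.append(f"<{_format_bound(boundaries[0])}")
        elif k == c:
            labels.append(f"≥{_format_bound(boundaries[-1])}")
        else:
            labels.append(
                f"{_format_bound(boundaries[k - 2])}–{_format_bound(boundaries[k - 1])}"
            )
    return ClassScheme(
        class_count=c,
        width=width,
        minimum=lo,
        maximum=hi,
        boundaries=boundaries,
        labels=tuple(labels),
    )


def assign_class(rounded_entropy: float, scheme: ClassScheme) -> int:
    """Map a rounded entropy to its 1-based class index.

    Values inside the range land in the class whose half-open interval
    contains them; values outside [min, max] take the nearest class (the
    first or the last), so prediction never fails on unseen patterns.
    """
    if scheme.class_count == 1:
        return 1
    return bisect_right(scheme.boundaries, rounded_entropy) + 1
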