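"""Ordered-polytomous EBE model: threshold response functions.

For an item with J ordered categories (1 = lowest), the model posits one
positive exponent per cut, kappa_{i,m} for m = 1..J-1, where m = 1 indexes the
TOP category and the exponents strictly decrease in m:

    Pr[x_i in top m categories | y] = y^{kappa_{i,m}},
    kappa_{i,1} > kappa_{i,2} > ... > kappa_{i,J-1} > 0.

Because y < 1, descending exponents make the cumulative probabilities increase
as the cut moves down, as they must.  Category probabilities are differences
of adjacent cumulatives, so every category's curve is single-peaked in y and
the model satisfies the joining assumption: collapsing adjacent categories
simply drops the interior threshold, and the collapsed probability is the sum
of its constituents.  With J = 2 the model reduces exactly to the dichotomous
response function y^k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    ResponsePattern,
    TraitDistribution,
    _as_pattern,
    signed_moment_sum,
)

__all__ = ["ThresholdSet", "category_prob", "category_terms", "poly_pattern_prob"]


@dataclass(frozen=True)
class ThresholdSet:
    """Per-item descending cumulative exponents for ordered categories.

    ``thresholds[i]`` holds (kappa_{i,1}, ..., kappa_{i,J_i-1}) with
    kappa_{i,1} the top-category exponent; strictly decreasing and positive.
    Items may have different numbers of categories (J_i = len + 1), and a
    single threshold per item recovers a dichotomous item.
    """

    thresholds: tuple[tuple[float, ...], ...]

    def __init__(self, thresholds: Sequence[Sequence[float]]):
        th = tuple(tuple(float(v) for v in t) for t in thresholds)
        for i, t in enumerate(th):
            if len(t) == 0:
                raise ValueError(f"item {i} has no thresholds")
            if any(v <= 0 for v in t):
                raise ValueError(f"item {i} thresholds must be positive: {t}")
            if any(t[m] <= t[m + 1] for m in range(len(t) - 1)):
                raise ValueError(
                    f"item {i} thresholds must strictly decrease "
                    f"(top category first): {t}"
                )
        object.__setattr__(self, "thresholds", th)

    def __len__(self) -> int:
        return len(self.thresholds)

    @property
    def n_categories(self) -> tuple[int, ...]:
        return tuple(len(t) + 1 for t in self.thresholds)


def category_terms(j: int, kappa: Sequence[float]) -> list[tuple[float, float]]:
    """Pr[x_i = j | y] as a signed list of (coefficient, exponent) pairs.

    With J = len(kappa) + 1 categories: the top category is y^{kappa_1}; the
    bottom is 1 - y^{kappa_{J-1}}; an interior category j is
    y^{kappa_{J-j}} - y^{kappa_{J-j-1}} (difference of adjacent cumulatives).
    """
    J = len(kappa) + 1
    if not 1 <= j <= J:
        raise ValueError(f"category {j} out of range 1..{J}")
    if j == J:
        return [(1.0, kappa[0])]
    if j == 1:
        return [(1.0, 0.0), (-1.0, kappa[J - 2])]
    # categories >= j are the top J-j+1, so Pr[x>=j|y] = y^{kappa[J-j]}
    return [(1.0, kappa[J - j]), (-1.0, kappa[J - j - 1])]


def category_prob(y: float, thresholds: ThresholdSet, item: int, j: int) -> float:
    """Conditional category probability Pr[x_item = j | y]."""
    if not (0.0 < y < 1.0):
        raise ValueError(f"trait value must lie in (0,1), got {y}")
    return sum(c * y**e for c, e in category_terms(j, thresholds.thresholds[item]))


def poly_pattern_prob(
    x: "ResponsePattern | Sequence[int]",
    thresholds: ThresholdSet,
    dist: TraitDistribution,
) -> float:
    """Exact marginal probability of an ordered-polytomous response pattern.

    Expands the product of per-item cumulative differences into at most 2^M
    signed Beta power moments; the dichotomous inclusion–exclusion sum is the
    special case where every item has a single threshold.
    """
    xv = _as_pattern(x)
    if len(xv) != len(thresholds):
        raise ValueError(
            f"pattern length {len(xv)} != number of items {len(thresholds)}"
        )
    terms = [
        category_terms(j, kappa) for j, kappa in zip(xv, thresholds.thresholds)
    ]
    return signed_moment_sum(terms, dist, context=f"pattern {xv}")
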