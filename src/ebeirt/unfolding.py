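"""Unfolding (ideal-point) EBE model: single-peaked response functions.

Instead of a monotone response curve, each item elicits a positive response
most readily from respondents whose trait sits at the item's location:

    Pr[x_i = 1 | y] = alpha_i * y^{k_i} * (1 - y^{k_i}),

a unimodal function of y peaking at y = 0.5^{1/k_i} with maximum alpha_i / 4.
With alpha_i = 4 the peak response probability is exactly 1.  Probabilities
remain valid for every y only when alpha_i <= 4; larger values are permitted
solely behind an explicit override for exploratory use.

Pattern probabilities again reduce to signed sums of Beta power moments: a
positive response contributes alpha*(y^k - y^{2k}) and a negative one
1 - alpha*y^k + alpha*y^{2k}, so the product expansion is the double
inclusion–exclusion over subsets of the zero set and, within each retained
item set, over which items contribute the squared term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import (
    ResponsePattern,
    TraitDistribution,
    _as_pattern,
    signed_moment_sum,
)

__all__ = ["UnfoldingParams", "unfolding_prob", "unfolding_item_terms", "unfolding_pattern_prob"]

#: Term-count cap: 2^|I(x)| x 2^|A ∪ C(x)| grows fast, so unfolding patterns
#: are limited to 12 items.
UNFOLDING_ITEM_CAP = 12


@dataclass(frozen=True)
class UnfoldingParams:
    """Item locations/scales and trait distribution for the unfolding model.

    Parameters
    ----------
    k : tuple of float
        Positive exponents; item i's peak location is 0.5**(1/k_i), so peak
        locations are ordered inversely to k.
    alpha : tuple of float
        Positive scale per item; the peak response probability is alpha/4.
        Values above 4 yield invalid probabilities for trait values near the
        peak and require ``allow_alpha_gt_4=True``.
    dist : TraitDistribution
    """

    k: tuple[float, ...]
    alpha: tuple[float, ...]
    dist: TraitDistribution

    def __init__(
        self,
        k: Sequence[float],
        alpha: "Sequence[float] | float",
        dist: TraitDistribution,
        allow_alpha_gt_4: bool = False,
    ):
        k = tuple(float(v) for v in k)
        if any(v <= 0 for v in k):
            raise ValueError(f"item exponents must be positive, got {k}")
        if isinstance(alpha, (int, float)):
            alpha = (float(alpha),) * len(k)
        alpha = tuple(float(v) for v in alpha)
        if len(alpha) != len(k):
            raise ValueError("alpha length must match k")
        if any(v <= 0 for v in alpha):
            raise ValueError(f"alpha must be positive, got {alpha}")
        if any(v > 4.0 for v in alpha) and not allow_alpha_gt_4:
            raise ValueError(
                "alpha > 4 makes the peak response probability exceed 1; "
                "pass allow_alpha_gt_4=True to override"
            )
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "dist", dist)

    def __len__(self) -> int:
        return len(self.k)


def unfolding_prob(y: float, k: float, alpha: float) -> float:
    """Single-peaked response probability alpha * y^k * (1 - y^k)."""
    if not (0.0 < y < 1.0):
        raise ValueError(f"trait value must lie in (0,1), got {y}")
    if k <= 0 or alpha <= 0:
        raise ValueError(f"k and alpha must be positive, got k={k}, alpha={alpha}")
    p = y**k
    return alpha * p * (1.0 - p)


def unfolding_item_terms(
    x_i: int, k_i: float, alpha_i: float
) -> list[tuple[float, float]]:
    """(coefficient, exponent) terms of Pr[x_i | y] for the unfolding model."""
    if x_i == 1:
        return [(alpha_i, k_i), (-alpha_i, 2.0 * k_i)]
    if x_i == 0:
        return [(1.0, 0.0), (-alpha_i, k_i), (alpha_i, 2.0 * k_i)]
    raise ValueError(f"dichotomous response must be 0 or 1, got {x_i}")


def unfolding_pattern_prob(
    x: "ResponsePattern | Sequence[int]",
    params: UnfoldingParams,
) -> float:
    """Exact marginal probability of a pattern under the unfolding model.

    Each item contributes two (positive response) or three (negative) signed
    power terms, so the expansion has at most 3^M Beta moments; equivalent to
    the nested inclusion–exclusion over the zero set and the squared-term
    subsets.
    """
    xv = _as_pattern(x)
    if len(xv) != len(params):
        raise ValueError(
            f"pattern length {len(xv)} != number of items {len(params)}"
        )
    if len(xv) > UNFOLDING_ITEM_CAP:
        raise ValueError(
            f"unfolding expansion limited to {UNFOLDING_ITEM_CAP} items "
            f"(term count grows as 3^M), got {len(xv)}"
        )
    terms = [
        unfolding_item_terms(xi, ki, ai)
        for xi, ki, ai in zip(xv, params.k, params.alpha)
    ]
    return signed_moment_sum(terms, params.dist, context=f"pattern {xv}")
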