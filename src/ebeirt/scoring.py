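"""Posterior trait scores E[y|x] and their variances.

The posterior density of the trait given a response pattern is
h(y|x) = Pr[x|y] phi(y) / Pr[x].  Because Pr[x|y] is a signed polynomial in
powers of y, the posterior moments are ratios of the same signed-moment
expansion with every exponent shifted: E[y|x] uses a +1 shift in the
numerator, E[y^2|x] a +2 shift.  No quadrature is involved; the computation
is exact up to floating point and shares the subset enumeration with the
pattern probability itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import (
    ItemParams,
    ResponsePattern,
    TraitDistribution,
    _as_pattern,
    dichotomous_item_terms,
    signed_moment_sum,
)
from .estimation import FitResult
from .polytomous import ThresholdSet, category_terms
from .unfolding import UnfoldingParams, unfolding_item_terms

__all__ = ["PosteriorScore", "posterior_score", "score_table"]


@dataclass(frozen=True)
class PosteriorScore:
    """EAP score for one response pattern: posterior mean, variance, Pr[x]."""

    pattern: tuple[int, ...]
    mean: float
    variance: float
    pattern_prob: float
    group: str | None = None


def _item_terms(x, items, dist):
    xv = _as_pattern(x)
    if isinstance(items, ItemParams):
        if len(xv) != len(items):
            raise ValueError(f"pattern length {len(xv)} != {len(items)} items")
        return xv, [dichotomous_item_terms(xi, ki) for xi, ki in zip(xv, items.k)], dist
    if isinstance(items, ThresholdSet):
        if len(xv) != len(items):
            raise ValueError(f"pattern length {len(xv)} != {len(items)} items")
        return xv, [category_terms(j, kp) for j, kp in zip(xv, items.thresholds)], dist
    if isinstance(items, UnfoldingParams):
        if len(xv) != len(items):
            raise ValueError(f"pattern length {len(xv)} != {len(items)} items")
        terms = [
            unfolding_item_terms(xi, ki, ai)
            for xi, ki, ai in zip(xv, items.k, items.alpha)
        ]
        return xv, terms, items.dist
    raise TypeError(f"unsupported item parameter object {type(items)!r}")


def posterior_score(
    x: "ResponsePattern | Sequence[int]",
    items: "ItemParams | ThresholdSet | UnfoldingParams",
    dist: TraitDistribution | None = None,
) -> PosteriorScore:
    """Posterior mean and variance of the trait given a response pattern.

    Works for all three variants; an empty pattern returns the prior moments
    a/(a+b) and ab/((a+b)^2 (a+b+1)).  The variance is clipped at zero to
    absorb last-digit roundoff in the moment ratio.
    """
    if dist is None and isinstance(items, UnfoldingParams):
        dist = items.dist
    xv, terms, dist = _item_terms(x, items, dist)
    ctx = f"pattern {xv}"
    denom = signed_moment_sum(terms, dist, shift=0.0, context=ctx)
    m1 = signed_moment_sum(terms, dist, shift=1.0, context=ctx) / denom
    m2 = signed_moment_sum(terms, dist, shift=2.0, context=ctx) / denom
    group = x.group if isinstance(x, ResponsePattern) else None
    return PosteriorScore(
        pattern=xv,
        mean=m1,
        variance=max(m2 - m1 * m1, 0.0),
        pattern_prob=denom,
        group=group,
    )


def score_table(table, fit: FitResult) -> list[PosteriorScore]:
    """One :class:`PosteriorScore` per distinct pattern in a fitted table."""
    out: list[PosteriorScore] = []
    models = {g: fit.group_model(g) for g in fit.spec.groups}
    for i, pat in enumerate(table.patterns):
        g = table.groups[i] if table.groups else fit.spec.groups[0]
        params, dist = models[g]
        s = posterior_score(pat, params, dist)
        out.append(PosteriorScore(s.pattern, s.mean, s.variance, s.pattern_prob, g))
    return out
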