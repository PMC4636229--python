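"""Synthetic response generation for all three EBE variants.

Each simulated respondent gets one latent trait draw y ~ Beta(a, b); item
responses are then conditionally independent given y: Bernoulli(y^k) for the
dichotomous model, the cumulative-difference category masses for the
polytomous model, and Bernoulli(alpha*y^k*(1-y^k)) for the unfolding model.
A single random stream is used with a fixed draw order (trait first, then
items in index order) so identical seed + configuration always reproduces the
same table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    ItemParams,
    PatternTable,
    TraitDistribution,
    _check_enumeration_cap,
    enumerate_patterns,
    pattern_prob,
)
from .polytomous import ThresholdSet, category_terms, poly_pattern_prob
from .unfolding import UnfoldingParams, unfolding_pattern_prob

__all__ = ["GroupTruth", "SimConfig", "simulate", "population_table"]


@dataclass(frozen=True)
class GroupTruth:
    """True parameters and sample size for one simulated group."""

    n: int
    items: "ItemParams | ThresholdSet | UnfoldingParams"
    dist: TraitDistribution | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group sample size must be >= 1, got {self.n}")
        if isinstance(self.items, UnfoldingParams):
            if any(a > 4.0 for a in self.items.alpha):
                raise ValueError(
                    "cannot simulate unfolding responses with alpha > 4: "
                    "the response function exceeds 1"
                )
            if self.dist is None:
                object.__setattr__(self, "dist", self.items.dist)
        if self.dist is None:
            raise ValueError("dist is required for non-unfolding variants")


@dataclass(frozen=True)
class SimConfig:
    """Variant, per-group truths (ordered), item labels and RNG seed."""

    variant: str
    groups: Mapping[str, GroupTruth]
    item_labels: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", dict(self.groups))
        first = next(iter(self.groups.values()))
        M = len(first.items)
        labels = tuple(self.item_labels) or tuple(
            f"item{i + 1}" for i in range(M)
        )
        if len(labels) != M:
            raise ValueError("item_labels length must match number of items")
        object.__setattr__(self, "item_labels", labels)


def _sample_pattern(rng, y: float, items, variant: str) -> tuple[int, ...]:
    if variant == "dichotomous":
        return tuple(int(rng.random() < y**k) for k in items.k)
    if variant == "polytomous":
        out = []
        for kappa in items.thresholds:
            J = len(kappa) + 1
            u = rng.random()
            cum = 0.0
            cat = J
            for j in range(1, J + 1):
                cum += sum(c * y**e for c, e in category_terms(j, kappa))
                if u < cum:
                    cat = j
                    break
            out.append(cat)
        return tuple(out)
    # unfolding
    return tuple(
        int(rng.random() < a * y**k * (1.0 - y**k))
        for k, a in zip(items.k, items.alpha)
    )


def simulate(config: SimConfig) -> PatternTable:
    """Draw a pattern-frequency table from known parameters.

    Deterministic given (seed, config); one Beta trait draw per respondent,
    then items in index order.
    """
    rng = np.random.default_rng(config.seed)
    patterns: list[tuple[int, ...]] = []
    counts: list[float] = []
    groups: list[str] = []
    for glabel, truth in config.groups.items():
        tally: Counter = Counter()
        a, b = truth.dist.a, truth.dist.b
        for _ in range(truth.n):
            y = rng.beta(a, b)
            tally[_sample_pattern(rng, y, truth.items, config.variant)] += 1
        for pat, c in sorted(tally.items()):
            patterns.append(pat)
            counts.append(float(c))
            groups.append(glabel)
    multi = len(config.groups) > 1
    first = next(iter(config.groups.values()))
    if config.variant == "polytomous":
        n_cat = first.items.n_categories
    else:
        n_cat = (2,) * len(first.items)
    return PatternTable(
        patterns=patterns,
        counts=np.array(counts),
        item_labels=config.item_labels,
        n_categories=n_cat,
        groups=groups if multi else None,
    )


def population_table(
    items: "ItemParams | ThresholdSet | UnfoldingParams",
    dist: TraitDistribution | None = None,
    item_labels: Sequence[str] | None = None,
) -> PatternTable:
    """Noise-free table whose 'counts' are the exact pattern probabilities.

    Useful as an infinite-sample oracle: feeding it to the start-value
    inversion recovers Theta = a + b exactly, and ML refits recover the true
    parameters up to optimizer tolerance.
    """
    M = len(items)
    _check_enumeration_cap(M)
    if isinstance(items, ItemParams):
        n_cat = (2,) * M
        prob = lambda p: pattern_prob(p, items, dist)
    elif isinstance(items, ThresholdSet):
        n_cat = items.n_categories
        prob = lambda p: poly_pattern_prob(p, items, dist)
    elif isinstance(items, UnfoldingParams):
        n_cat = (2,) * M
        prob = lambda p: unfolding_pattern_prob(p, items)
    else:
        raise TypeError(f"unsupported item parameter object {type(items)!r}")
    pats = list(enumerate_patterns(n_cat))
    counts = np.array([prob(p) for p in pats])
    labels = tuple(item_labels) if item_labels else tuple(
        f"item{i + 1}" for i in range(M)
    )
    return PatternTable(
        patterns=pats, counts=counts, item_labels=labels, n_categories=n_cat
    )
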