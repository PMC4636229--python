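"""Core probability machinery for the extended binomial error (EBE) model.

The EBE model describes dichotomous responses through the response function

    Pr[x_i = 1 | y] = y^{k_i},        k_i > 0,  0 < y < 1,

where ``y`` is a latent trait interpretable as the probability of endorsing a
standardized (k = 1) item and ``k_i`` is the hardness of item ``i``.  The trait
is given a two-parameter Beta(a, b) distribution.  Under conditional
independence, the marginal probability of any response pattern is an
alternating (inclusion–exclusion) sum of Beta power moments

    E[y^k] = B(a + k, b) / B(a, b),

which this module evaluates exactly on the log-gamma scale with compensated
summation.  The same signed-moment expansion drives the ordered-polytomous and
unfolding variants (see :mod:`ebeirt.polytomous` and :mod:`ebeirt.unfolding`);
here each item contributes a small list of ``(coefficient, exponent)`` terms
and the pattern probability is the expectation of their product.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "TraitDistribution",
    "ItemParams",
    "ResponsePattern",
    "PatternTable",
    "NumericalInstabilityError",
    "EnumerationCapError",
    "beta_power_moment",
    "log_beta_power_moment",
    "pattern_prob",
    "pattern_log_prob",
    "all_pattern_probs",
    "to_unbounded",
    "from_unbounded",
    "signed_moment_sum",
    "dichotomous_item_terms",
    "enumerate_patterns",
]

#: Hard cap on the number of items for exhaustive pattern enumeration and for
#: inclusion–exclusion expansions (2^M signed terms per pattern).
ENUMERATION_CAP = 20

#: Above this many items a warning is emitted: cost grows as 2^M.
ENUMERATION_WARN = 12

#: Floor applied to pattern probabilities inside likelihood evaluation only
#: (never in the public probability API) so that line searches survive extreme
#: parameter proposals.
LIKELIHOOD_PROB_FLOOR = 1e-300


class NumericalInstabilityError(ArithmeticError):
    """Raised when an alternating moment sum collapses to a nonpositive value.

    The inclusion–exclusion representation of a pattern probability is an
    alternating series; with extreme parameters catastrophic cancellation can
    leave a nonpositive total even though the true probability is positive.
    """


class EnumerationCapError(ValueError):
    """Raised when a request would enumerate more patterns than the cap allows."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitDistribution:
    """Beta(a, b) distribution of the latent trait y on (0, 1).

    Parameters
    ----------
    a, b : float
        Strictly positive Beta shape parameters.  The prior trait mean is
        ``a / (a + b)`` and the variance ``ab / ((a+b)^2 (a+b+1))``.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(
                f"Beta shape parameters must be positive, got a={self.a}, b={self.b}"
            )

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def variance(self) -> float:
        s = self.a + self.b
        return self.a * self.b / (s * s * (s + 1.0))


@dataclass(frozen=True)
class ItemParams:
    """Item hardness exponents for the dichotomous model.

    Parameters
    ----------
    k : sequence of float
        One strictly positive hardness per item; larger ``k`` makes the item
        harder (``Pr[x=1] = E[y^k]`` decreases in ``k``).
    fixed_mask : sequence of bool, optional
        Marks items whose hardness is a normalization constraint (k_i = 1).
        Purely descriptive here; estimation enforces the constraint.
    """

    k: tuple[float, ...]
    fixed_mask: tuple[bool, ...] = ()

    def __init__(self, k: Sequence[float], fixed_mask: Sequence[bool] | None = None):
        k = tuple(float(v) for v in k)
        if any(v <= 0 for v in k):
            raise ValueError(f"item hardnesses must be positive, got {k}")
        if fixed_mask is None:
            fixed_mask = (False,) * len(k)
        fixed_mask = tuple(bool(v) for v in fixed_mask)
        if len(fixed_mask) != len(k):
            raise ValueError("fixed_mask length must match k")
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "fixed_mask", fixed_mask)

    def __len__(self) -> int:
        return len(self.k)


@dataclass(frozen=True)
class ResponsePattern:
    """A single response pattern: one category code per item.

    Dichotomous items use codes {0, 1} with 1 = positive/agree; polytomous
    items use 1..J with 1 the lowest category.
    """

    x: tuple[int, ...]
    group: str | None = None

    def __init__(self, x: Sequence[int], group: str | None = None):
        object.__setattr__(self, "x", tuple(int(v) for v in x))
        object.__setattr__(self, "group", group)

    def __len__(self) -> int:
        return len(self.x)


def _as_pattern(x: "ResponsePattern | Sequence[int]") -> tuple[int, ...]:
    if isinstance(x, ResponsePattern):
        return x.x
    return tuple(int(v) for v in x)


@dataclass
class PatternTable:
    """Observed response patterns with frequencies, optionally per group.

    Parameters
    ----------
    patterns : list of tuple of int
        Distinct response patterns (within each group).
    counts : array of float
        Nonnegative frequency for each pattern.  Real-valued counts are
        allowed so that exact population tables (expected proportions) can be
        fed through the same interfaces.
    item_labels : sequence of str
    n_categories : sequence of int
        Number of response categories per item (2 for dichotomous).
    groups : sequence of str, optional
        Group label per row; ``None`` for single-group data.
    """

    patterns: list[tuple[int, ...]]
    counts: np.ndarray
    item_labels: tuple[str, ...]
    n_categories: tuple[int, ...]
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        self.patterns = [tuple(int(v) for v in p) for p in self.patterns]
        self.counts = np.asarray(self.counts, dtype=float)
        self.item_labels = tuple(self.item_labels)
        self.n_categories = tuple(int(j) for j in self.n_categories)
        if len(self.item_labels) != len(self.n_categories):
            raise ValueError("item_labels and n_categories length mismatch")
        if len(self.patterns) != len(self.counts):
            raise ValueError("patterns and counts length mismatch")
        if len(self.patterns) == 0:
            raise ValueError("empty pattern table")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        M = len(self.item_labels)
        dich = all(j == 2 for j in self.n_categories)
        for p in self.patterns:
            if len(p) != M:
                raise ValueError(f"pattern {p} has wrong length (expected {M})")
            for v, j in zip(p, self.n_categories):
                lo = 0 if dich else 1
                hi = 1 if dich else j
                if not (lo <= v <= hi):
                    raise ValueError(
                        f"category code {v} out of range [{lo}, {hi}] in pattern {p}"
                    )
        if self.groups is not None:
            self.groups = [str(g) for g in self.groups]
            if len(self.groups) != len(self.patterns):
                raise ValueError("groups and patterns length mismatch")
        seen: set[tuple] = set()
        for i, p in enumerate(self.patterns):
            key = (self.groups[i] if self.groups else None, p)
            if key in seen:
                raise ValueError(f"duplicate pattern {p} within group {key[0]}")
            seen.add(key)

    @property
    def M(self) -> int:
        return len(self.item_labels)

    @property
    def N(self) -> float:
        return float(self.counts.sum())

    @property
    def group_labels(self) -> tuple[str, ...]:
        if self.groups is None:
            return ("all",)
        out: list[str] = []
        for g in self.groups:
            if g not in out:
                out.append(g)
        return tuple(out)

    def group_table(self, label: str) -> "PatternTable":
        """Single-group slice (returns self for single-group tables)."""
        if self.groups is None:
            if label != "all":
                raise KeyError(label)
            return self
        idx = [i for i, g in enumerate(self.groups) if g == label]
        if not idx:
            raise KeyError(label)
        return PatternTable(
            patterns=[self.patterns[i] for i in idx],
            counts=self.counts[idx],
            item_labels=self.item_labels,
            n_categories=self.n_categories,
            groups=None,
        )

    @property
    def n_cells(self) -> int:
        """Number of possible patterns per group (product of category counts)."""
        out = 1
        for j in self.n_categories:
            out *= j
        return out

    def marginal(self, i: int, group: str | None = None) -> float:
        """Observed proportion of positive responses on dichotomous item i."""
        t = self if group is None else self.group_table(group)
        w = sum(c for p, c in zip(t.patterns, t.counts) if p[i] == 1)
        return w / t.N

    def joint(self, i: int, j: int, group: str | None = None) -> float:
        """Observed proportion with x_i = 1 and x_j = 1."""
        t = self if group is None else self.group_table(group)
        w = sum(c for p, c in zip(t.patterns, t.counts) if p[i] == 1 and p[j] == 1)
        return w / t.N


# ---------------------------------------------------------------------------
# Beta power moments and the bounded <-> unbounded transforms
# ---------------------------------------------------------------------------


def log_beta_power_moment(a: float, b: float, k: float) -> float:
    """log E[y^k] for y ~ Beta(a, b), via log-gamma.

    E[y^k] = Gamma(a+b) Gamma(a+k) / (Gamma(a) Gamma(a+b+k)) = B(a+k, b)/B(a, b),
    valid for any real k >= 0 (not just integers).
    """
    if not (a > 0 and b > 0):
        raise ValueError(f"invalid Beta distribution a={a}, b={b}")
    if k < 0:
        raise ValueError(f"moment order must be nonnegative, got k={k}")
    return gammaln(a + b) + gammaln(a + k) - gammaln(a) - gammaln(a + b + k)


def beta_power_moment(dist: TraitDistribution, k: float) -> float:
    """Fractional power moment E[y^k] in (0, 1] for y ~ Beta(a, b)."""
    return math.exp(log_beta_power_moment(dist.a, dist.b, k))


def to_unbounded(value: float, which: str = "trait") -> float:
    """Map a bounded model parameter to the unbounded double-exponential scale.

    Traits use ``xi = -log(-log y)`` (y in (0,1)); item hardnesses use
    ``chi = log k`` (k > 0).  On this scale the dichotomous response function
    reads ``Pr[x=1 | xi] = exp(-exp(-(xi - chi)))``, which equals 0.5 at
    ``xi - chi = -log(log 2) ≈ +0.3665``.  The unfolding variant instead uses
    ``xi = -log(-2 log y)`` (``which="trait_unfolding"``) so that its response
    peak sits at ``xi = chi``.
    """
    if which == "trait":
        if not (0.0 < value < 1.0):
            raise ValueError(f"trait value must lie in (0,1), got {value}")
        return -math.log(-math.log(value))
    if which == "trait_unfolding":
        if not (0.0 < value < 1.0):
            raise ValueError(f"trait value must lie in (0,1), got {value}")
        return -math.log(-2.0 * math.log(value))
    if which == "item":
        if not value > 0:
            raise ValueError(f"item hardness must be positive, got {value}")
        return math.log(value)
    raise ValueError(f"unknown transform target {which!r}")


def from_unbounded(value: float, which: str = "trait") -> float:
    """Inverse of :func:`to_unbounded`."""
    if which == "trait":
        return math.exp(-math.exp(-value))
    if which == "trait_unfolding":
        return math.exp(-0.5 * math.exp(-value))
    if which == "item":
        return math.exp(value)
    raise ValueError(f"unknown transform target {which!r}")


# ---------------------------------------------------------------------------
# Signed-moment expansions
# ---------------------------------------------------------------------------

# An "item term list" is a list of (coefficient, exponent) pairs such that
# Pr[x_i | y] = sum_t coef_t * y^{exp_t}.  The product over items expands into
# a signed sum of Beta power moments; for dichotomous items this is exactly
# the inclusion-exclusion sum over subsets of the zero set I(x).


def dichotomous_item_terms(x_i: int, k_i: float) -> list[tuple[float, float]]:
    """Terms of Pr[x_i | y] = y^k (positive) or 1 - y^k (negative response)."""
    if x_i == 1:
        return [(1.0, k_i)]
    if x_i == 0:
        return [(1.0, 0.0), (-1.0, k_i)]
    raise ValueError(f"dichotomous response must be 0 or 1, got {x_i}")


def signed_moment_sum(
    item_terms: Sequence[Sequence[tuple[float, float]]],
    dist: TraitDistribution,
    shift: float = 0.0,
    context: str = "pattern",
) -> float:
    """Exact expectation of a product of per-item polynomial-in-y^k terms.

    Computes ``E[ y^shift * prod_i Pr[x_i | y] ]`` where each factor is given
    as a list of ``(coefficient, exponent)`` pairs.  Every cross term is a
    Beta power moment evaluated on the log-gamma scale; the alternating sum is
    accumulated with :func:`math.fsum` (round-off-free compensated summation).

    The ``shift`` argument raises every exponent by a constant, which is how
    posterior moments E[y^s * Pr[x|y]] are obtained from the same expansion.

    Raises
    ------
    NumericalInstabilityError
        If cancellation drives the total to a nonpositive value.
    """
    n_terms = 1
    for t in item_terms:
        n_terms *= len(t)
    if n_terms > (1 << ENUMERATION_CAP):
        raise EnumerationCapError(
            f"moment expansion would need {n_terms} terms (cap 2^{ENUMERATION_CAP})"
        )
    a, b = dist.a, dist.b
    terms = []
    for combo in itertools.product(*item_terms):
        coef = 1.0
        expo = shift
        for c, e in combo:
            coef *= c
            expo += e
        if coef != 0.0:
            terms.append(coef * math.exp(log_beta_power_moment(a, b, expo)))
    total = math.fsum(terms)
    if total <= 0.0:
        raise NumericalInstabilityError(
            f"alternating moment sum for {context} collapsed to {total!r}; "
            "the inclusion-exclusion series cancelled catastrophically"
        )
    return total


def pattern_prob(
    x: "ResponsePattern | Sequence[int]",
    items: ItemParams,
    dist: TraitDistribution,
) -> float:
    """Exact marginal probability of a dichotomous response pattern.

    Pr[x] = sum over subsets A of the zero set I(x) of
    (-1)^|A| E[y^{sum_{i in A ∪ C(x)} k_i}].
    """
    xv = _as_pattern(x)
    if len(xv) != len(items):
        raise ValueError(
            f"pattern length {len(xv)} != number of items {len(items)}"
        )
    terms = [dichotomous_item_terms(xi, ki) for xi, ki in zip(xv, items.k)]
    return signed_moment_sum(terms, dist, context=f"pattern {xv}")


def pattern_log_prob(
    x: "ResponsePattern | Sequence[int]",
    items: ItemParams,
    dist: TraitDistribution,
) -> float:
    """log Pr[x] for a dichotomous pattern (see :func:`pattern_prob`)."""
    return math.log(pattern_prob(x, items, dist))


def enumerate_patterns(n_categories: Sequence[int]) -> Iterator[tuple[int, ...]]:
    """All possible patterns: {0,1}^M for dichotomous, {1..J}^M otherwise."""
    ranges = []
    for j in n_categories:
        if j == 2:
            ranges.append(range(2))
        else:
            ranges.append(range(1, j + 1))
    return itertools.product(*ranges)


def _check_enumeration_cap(M: int) -> None:
    if M > ENUMERATION_CAP:
        raise EnumerationCapError(
            f"refusing to enumerate 2^{M} patterns (cap {ENUMERATION_CAP}); "
            "cost is 2^M patterns x 2^|I(x)| inclusion-exclusion terms"
        )
    if M > ENUMERATION_WARN:
        warnings.warn(
            f"enumerating 2^{M} patterns; this grows exponentially in M",
            stacklevel=3,
        )


def all_pattern_probs(
    items: ItemParams,
    dist: TraitDistribution,
    M: int | None = None,
) -> dict[tuple[int, ...], float]:
    """Probabilities of all 2^M dichotomous patterns (they sum to one)."""
    if M is None:
        M = len(items)
    if M != len(items):
        raise ValueError("M must equal the number of items")
    _check_enumeration_cap(M)
    return {
        p: pattern_prob(p, items, dist) for p in enumerate_patterns((2,) * M)
    }
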