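"""Full-information maximum-likelihood estimation for EBE models.

Fits any of the three model variants (dichotomous, ordered-polytomous,
unfolding) to pattern-frequency tables, single- or multi-group, under
arbitrary fix/share constraints on the parameters.  Estimation maximizes the
multinomial log-likelihood over observed pattern counts, with all positive
parameters optimized on an unbounded transformed scale:

* hardnesses k, Beta shapes a and b, and top thresholds: log scale;
* subsequent (descending) threshold ratios in (0, 1): logit scale, which keeps
  every optimizer iterate correctly ordered;
* free unfolding scales alpha in (0, 4]: scaled-logit.

The default search is quasi-Newton (BFGS) with numerical gradients, followed
by a Nelder–Mead simplex polish, keeping whichever optimum is better; a
conjugate-gradient (Polak–Ribiere) first stage is available via
``FitOptions(method="cg")``.  Start values come from the closed-form
bivariate-table inversion (see :func:`start_values`).

Fit is assessed against the saturated multinomial: the likelihood-ratio
chi-square L^2 = 2 sum obs*log(obs/expected) over observed cells, with
df = sum_g (cells_g - 1) - n_free counting all possible cells, and Raftery's
BIC = L^2 - df*ln(N) (pooled N across groups).
"""

from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import chi2

from .core import (
    ItemParams,
    LIKELIHOOD_PROB_FLOOR,
    NumericalInstabilityError,
    PatternTable,
    TraitDistribution,
    beta_power_moment,
    log_beta_power_moment,
    pattern_prob,
)
from .polytomous import ThresholdSet, poly_pattern_prob
from .unfolding import UnfoldingParams, unfolding_pattern_prob

__all__ = [
    "ModelSpec",
    "FitOptions",
    "FitResult",
    "ParameterIndex",
    "start_values",
    "negative_loglik",
    "fit_ml",
    "standard_errors",
    "lr_fit_stats",
    "nested_lr_test",
]

logger = logging.getLogger("ebeirt")

VARIANTS = ("dichotomous", "polytomous", "unfolding")


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of which parameters are fixed, free or shared.

    Parameter names
    ---------------
    * ``"k:LABEL"`` — hardness of item LABEL (dichotomous and unfolding);
    * ``"kappa:LABEL:1"`` — top-category threshold of a polytomous item (the
      only threshold that may be fixed; lower thresholds are parameterized as
      descending ratios and are always free);
    * ``"kappa:LABEL"`` — in ``shared``, shares ALL thresholds of an item
      across groups;
    * ``"a"``, ``"b"`` — Beta trait shapes;
    * ``alpha_mode`` — unfolding scale handling: ``"fixed"`` (all alpha at
      ``alpha_value``), ``"shared"`` (one free alpha for all items), or
      ``"free"`` (one free alpha per item, common across groups), each bounded
      in (0, 4].

    Entries in ``fixed`` apply in every group; names in ``shared`` constrain
    the corresponding parameter equal across groups.
    """

    variant: str
    item_labels: tuple[str, ...]
    n_categories: tuple[int, ...]
    groups: tuple[str, ...] = ("all",)
    fixed: Mapping[str, float] = field(default_factory=dict)
    shared: frozenset[str] = frozenset()
    alpha_mode: str = "fixed"
    alpha_value: float = 4.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        object.__setattr__(self, "item_labels", tuple(self.item_labels))
        object.__setattr__(self, "n_categories", tuple(int(j) for j in self.n_categories))
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "fixed", dict(self.fixed))
        object.__setattr__(self, "shared", frozenset(self.shared))
        if len(self.item_labels) != len(self.n_categories):
            raise ValueError("item_labels and n_categories length mismatch")
        if self.variant != "polytomous" and any(j != 2 for j in self.n_categories):
            raise ValueError(f"{self.variant} items must have 2 categories")
        if self.alpha_mode not in ("fixed", "shared", "free"):
            raise ValueError(f"unknown alpha_mode {self.alpha_mode!r}")
        known = self._known_names()
        for name in list(self.fixed) + list(self.shared):
            if name not in known:
                raise ValueError(f"unknown parameter name {name!r}; known: {sorted(known)}")
        for name, v in self.fixed.items():
            if not (float(v) > 0):
                raise ValueError(f"fixed value for {name} must be positive, got {v}")

    def _known_names(self) -> set[str]:
        names = {"a", "b"}
        if self.variant == "unfolding":
            names.add("alpha")
        for lab, J in zip(self.item_labels, self.n_categories):
            if self.variant == "polytomous":
                names.add(f"kappa:{lab}")
                names.add(f"kappa:{lab}:1")
            else:
                names.add(f"k:{lab}")
            if self.variant == "unfolding":
                names.add(f"alpha:{lab}")
        return names

    @classmethod
    def from_table(
        cls,
        table: PatternTable,
        variant: str = "dichotomous",
        anchor: str | None = None,
        fixed: Mapping[str, float] | None = None,
        shared: Sequence[str] = (),
        alpha_mode: str = "fixed",
        alpha_value: float = 4.0,
    ) -> "ModelSpec":
        """Build a spec from a table, anchoring one item unless told otherwise.

        ``anchor`` names the item whose (top) hardness is fixed at 1 to set
        the trait scale; it defaults to the last item when ``fixed`` contains
        no item-side constraint.
        """
        fixed = dict(fixed or {})
        item_side = [n for n in fixed if n not in ("a", "b", "alpha")]
        if not item_side:
            lab = anchor if anchor is not None else table.item_labels[-1]
            if lab not in table.item_labels:
                raise ValueError(f"anchor item {lab!r} not in table items {table.item_labels}")
            name = f"kappa:{lab}:1" if variant == "polytomous" else f"k:{lab}"
            fixed[name] = 1.0
        elif anchor is not None and item_side:
            raise ValueError("give either anchor or explicit item-side fixed values, not both")
        return cls(
            variant=variant,
            item_labels=table.item_labels,
            n_categories=table.n_categories if variant == "polytomous" else (2,) * table.M,
            groups=table.group_labels,
            fixed=fixed,
            shared=frozenset(shared),
            alpha_mode=alpha_mode,
            alpha_value=alpha_value,
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "variant": self.variant,
            "item_labels": list(self.item_labels),
            "n_categories": list(self.n_categories),
            "groups": list(self.groups),
            "fixed": dict(self.fixed),
            "shared": sorted(self.shared),
            "alpha_mode": self.alpha_mode,
            "alpha_value": self.alpha_value,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelSpec":
        return cls(
            variant=d["variant"],
            item_labels=tuple(d["item_labels"]),
            n_categories=tuple(d["n_categories"]),
            groups=tuple(d.get("groups", ("all",))),
            fixed=dict(d.get("fixed", {})),
            shared=frozenset(d.get("shared", ())),
            alpha_mode=d.get("alpha_mode", "fixed"),
            alpha_value=float(d.get("alpha_value", 4.0)),
        )


# ---------------------------------------------------------------------------
# Parameter slots: mapping between the free vector and natural parameters
# ---------------------------------------------------------------------------


def _transform(kind: str, theta: float) -> float:
    if kind == "log":
        return math.exp(theta)
    if kind == "logit":
        return float(expit(theta))
    if kind == "alpha4":
        return 4.0 * float(expit(theta))
    raise ValueError(kind)


def _inverse_transform(kind: str, value: float) -> float:
    if kind == "log":
        if not value > 0:
            raise ValueError(f"log-scale slot needs a positive value, got {value}")
        return math.log(value)
    if kind == "logit":
        if not 0.0 < value < 1.0:
            raise ValueError(f"logit-scale slot needs a value in (0,1), got {value}")
        return float(logit(value))
    if kind == "alpha4":
        if not 0.0 < value < 4.0:
            raise ValueError(f"alpha slot needs a value in (0,4), got {value}")
        return float(logit(value / 4.0))
    raise ValueError(kind)


@dataclass(frozen=True)
class _Slot:
    id: str
    transform: str
    fixed: float | None = None
    index: int | None = None  # position in the free vector, None if fixed


class ParameterIndex:
    """Resolves a ModelSpec into optimizer slots and natural parameters."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self._slots: dict[str, _Slot] = {}
        # (group, role-key) -> slot id; role keys are internal
        self._map: dict[tuple[str, str], str] = {}
        n_free = 0

        def add(key: str, group: str, slot_id: str, transform: str, fixed: float | None):
            nonlocal n_free
            if slot_id not in self._slots:
                index = None
                if fixed is None:
                    index = n_free
                    n_free += 1
                self._slots[slot_id] = _Slot(slot_id, transform, fixed, index)
            self._map[(group, key)] = slot_id

        def slot_name(base: str, group: str, is_shared: bool) -> str:
            if is_shared or len(spec.groups) == 1:
                return base
            return f"{base}@{group}"

        for g in spec.groups:
            for lab, J in zip(spec.item_labels, spec.n_categories):
                if spec.variant == "polytomous":
                    shared = f"kappa:{lab}" in spec.shared
                    top = f"kappa:{lab}:1"
                    add(top, g, slot_name(top, g, shared), "log", spec.fixed.get(top))
                    for m in range(2, J):
                        key = f"r:{lab}:{m}"
                        add(key, g, slot_name(key, g, shared), "logit", None)
                else:
                    name = f"k:{lab}"
                    shared = name in spec.shared
                    add(name, g, slot_name(name, g, shared), "log", spec.fixed.get(name))
                    if spec.variant == "unfolding":
                        aname = f"alpha:{lab}"
                        if spec.alpha_mode == "fixed":
                            add(aname, g, "alpha", "alpha4", spec.alpha_value)
                        elif spec.alpha_mode == "shared":
                            add(aname, g, "alpha", "alpha4", spec.fixed.get("alpha"))
                        else:  # free per item, common across groups
                            add(aname, g, aname, "alpha4", None)
            for t in ("a", "b"):
                add(t, g, slot_name(t, g, t in spec.shared), "log", spec.fixed.get(t))

        self.n_free = n_free
        self.free_slots = sorted(
            (s for s in self._slots.values() if s.index is not None),
            key=lambda s: s.index,
        )

    # -- free vector <-> natural slot values ------------------------------

    def slot_values(self, theta: np.ndarray) -> dict[str, float]:
        """Natural value of every slot (fixed ones included)."""
        out = {}
        for s in self._slots.values():
            if s.index is None:
                out[s.id] = float(s.fixed)
            else:
                out[s.id] = _transform(s.transform, float(theta[s.index]))
        return out

    def pack(self, natural: Mapping[str, float]) -> np.ndarray:
        """Free vector from natural slot values (fixed slots ignored)."""
        theta = np.zeros(self.n_free)
        for s in self.free_slots:
            if s.id not in natural:
                raise KeyError(f"missing start value for slot {s.id!r}")
            theta[s.index] = _inverse_transform(s.transform, float(natural[s.id]))
        return theta

    # -- natural parameters per group --------------------------------------

    def group_params(self, theta: np.ndarray, group: str):
        """(model parameters object, TraitDistribution) for one group."""
        vals = self.slot_values(theta)
        spec = self.spec

        def v(key: str) -> float:
            return vals[self._map[(group, key)]]

        dist = TraitDistribution(v("a"), v("b"))
        if spec.variant == "dichotomous":
            k = [v(f"k:{lab}") for lab in spec.item_labels]
            mask = [f"k:{lab}" in spec.fixed for lab in spec.item_labels]
            return ItemParams(k, mask), dist
        if spec.variant == "polytomous":
            th = []
            for lab, J in zip(spec.item_labels, spec.n_categories):
                kappa = [v(f"kappa:{lab}:1")]
                for m in range(2, J):
                    kappa.append(kappa[-1] * v(f"r:{lab}:{m}"))
                th.append(kappa)
            return ThresholdSet(th), dist
        # unfolding
        k = [v(f"k:{lab}") for lab in spec.item_labels]
        alpha = [v(f"alpha:{lab}") for lab in spec.item_labels]
        return UnfoldingParams(k, alpha, dist, allow_alpha_gt_4=True), dist

    def natural_estimates(self, theta: np.ndarray) -> dict[str, dict[str, float]]:
        """Named natural-scale parameter values per group."""
        out: dict[str, dict[str, float]] = {}
        for g in self.spec.groups:
            params, dist = self.group_params(theta, g)
            d: dict[str, float] = {}
            if self.spec.variant == "polytomous":
                for lab, kappa in zip(self.spec.item_labels, params.thresholds):
                    for m, val in enumerate(kappa, start=1):
                        d[f"kappa:{lab}:{m}"] = val
            else:
                for lab, kv in zip(self.spec.item_labels, params.k):
                    d[f"k:{lab}"] = kv
                if self.spec.variant == "unfolding":
                    for lab, av in zip(self.spec.item_labels, params.alpha):
                        d[f"alpha:{lab}"] = av
            d["a"] = dist.a
            d["b"] = dist.b
            out[g] = d
        return out

    def is_natural_fixed(self, group: str, name: str) -> bool:
        """Whether a natural parameter is fully determined by fixed slots."""
        spec = self.spec
        if name.startswith("kappa:"):
            _, lab, m = name.split(":")
            keys = [f"kappa:{lab}:1"] + [f"r:{lab}:{mm}" for mm in range(2, int(m) + 1)]
        else:
            keys = [name]
        return all(self._slots[self._map[(group, k)]].fixed is not None for k in keys)

    def check_identified(self, table: PatternTable) -> None:
        avail = len(table.group_labels) * (table.n_cells - 1)
        if self.n_free > avail:
            raise ValueError(
                f"model is not identified: {self.n_free} free parameters but only "
                f"{avail} independent cells; fix or share more parameters "
                "(e.g. a fixed hardness anchor, or fixed alpha for unfolding)"
            )
        spec = self.spec
        # every trait scale needs an item-side anchor: the hardness scale is
        # only weakly identified otherwise (a power of a Beta variable is
        # nearly Beta, leaving a near-flat likelihood ridge); this applies to
        # the unfolding variant too, where a fixed alpha does not pin the
        # k scale
        anchored = any(n not in ("a", "b", "alpha") for n in spec.fixed)
        if not anchored:
            raise ValueError(
                "model is not identified: fix one item hardness (anchor) "
                "to set the trait scale"
            )


# ---------------------------------------------------------------------------
# Start values (closed-form inversion of bivariate 2x2 tables)
# ---------------------------------------------------------------------------


def _theta_root(p_ref: float, p_j: float, s_j: float) -> float | None:
    """Positive root Theta = a + b of the bivariate start-value equation.

    Solves  P_j = Gamma(T) Gamma(T(P_ref + S_j)) / (Gamma(T P_ref) Gamma(T(S_j + 1)))
    for T, i.e. P_j = E[y^{T S_j}] under Beta(T*P_ref, T*(1-P_ref)).
    """

    def f(log_t: float) -> float:
        t = math.exp(log_t)
        return math.log(p_j) - log_beta_power_moment(t * p_ref, t * (1.0 - p_ref), t * s_j)

    grid = np.linspace(math.log(1e-6), math.log(1e6), 241)
    fv = np.array([f(g) for g in grid])
    sign = np.sign(fv)
    changes = np.nonzero(np.diff(sign) != 0)[0]
    if len(changes) == 0:
        return None
    i = changes[0]
    root = optimize.brentq(f, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-12)
    return math.exp(root)


def start_values(
    table: PatternTable, ref_item: int | str | None = None
) -> dict[str, float]:
    """Closed-form start values for the dichotomous model from 2x2 margins.

    Normalizing k_ref = 1, each other item's cross-classification with the
    reference yields S_j = k_j / (a + b) from observed joint and marginal
    proportions; a single positive root Theta = a + b then follows from the
    reference marginal, and (a, b, k_j) are recovered as a = Theta*P_ref,
    b = Theta - a, k_j = Theta*S_j.  Thetas from the M-1 admissible item pairs
    are averaged.  Items with nonpositive association (S_j <= 0) are excluded
    from the average with a warning and seeded from the marginal-odds form
    k_j = a*(1 - P_j)/P_j instead.

    Returns a dict with keys ``k:LABEL``, ``a`` and ``b``.
    """
    if table.groups is not None and len(table.group_labels) > 1:
        raise ValueError("start_values expects a single-group table")
    if any(j != 2 for j in table.n_categories):
        raise ValueError("start_values expects dichotomous items")
    labels = table.item_labels
    if ref_item is None:
        ref = table.M - 1
    elif isinstance(ref_item, str):
        ref = labels.index(ref_item)
    else:
        ref = int(ref_item)
    p = [table.marginal(i) for i in range(table.M)]
    if not (0.0 < p[ref] < 1.0):
        raise ValueError(f"reference item marginal must lie in (0,1), got {p[ref]}")

    s_vals: dict[int, float] = {}
    thetas: list[float] = []
    excluded: list[int] = []
    for j in range(table.M):
        if j == ref:
            continue
        pj = p[j]
        pij = table.joint(ref, j)
        denom = pj - pij
        s_j = (pij - p[ref] * pj) / denom if denom > 0 else -1.0
        if s_j <= 0:
            excluded.append(j)
            continue
        s_vals[j] = s_j
        root = _theta_root(p[ref], pj, s_j)
        if root is not None:
            thetas.append(root)

    if thetas:
        theta = float(np.mean(thetas))
    else:
        warnings.warn(
            "no item pair gave a positive association with the reference; "
            "falling back to a=b=1 and marginal-odds hardnesses"
        )
        theta = 2.0
    a = theta * p[ref]
    b = theta - a
    out = {"a": a, "b": b}
    for j in range(table.M):
        if j == ref:
            out[f"k:{labels[j]}"] = 1.0
        elif j in s_vals:
            out[f"k:{labels[j]}"] = theta * s_vals[j]
        else:
            out[f"k:{labels[j]}"] = a * (1.0 - p[j]) / p[j]
    if excluded and thetas:
        warnings.warn(
            f"items {[labels[j] for j in excluded]} showed nonpositive association "
            "with the reference; excluded from Theta averaging and seeded from "
            "marginal odds"
        )
    return out


def _solve_exponent(dist: TraitDistribution, target: float) -> float:
    """kappa such that E[y^kappa] = target (monotone decreasing in kappa)."""
    target = min(max(target, 1e-9), 1.0 - 1e-9)

    def f(log_k: float) -> float:
        return log_beta_power_moment(dist.a, dist.b, math.exp(log_k)) - math.log(target)

    lo, hi = math.log(1e-8), math.log(1e6)
    if f(lo) < 0:  # even tiny kappa gives too small a moment: target ~ 1
        return 1e-8
    if f(hi) > 0:
        return 1e6
    return math.exp(optimize.brentq(f, lo, hi, xtol=1e-12))


def _default_starts(index: ParameterIndex, table: PatternTable) -> dict[str, float]:
    """Start values for every free slot, any variant, any group structure."""
    spec = index.spec
    acc: dict[str, list[float]] = {}

    def push(slot_id: str, value: float) -> None:
        acc.setdefault(slot_id, []).append(value)

    for g in spec.groups:
        gt = table.group_table(g)
        if spec.variant == "dichotomous":
            ref = None
            for i, lab in enumerate(spec.item_labels):
                if f"k:{lab}" in spec.fixed:
                    ref = i
                    break
            sv = start_values(gt, ref_item=ref)
            for lab in spec.item_labels:
                push(index._map[(g, f"k:{lab}")], sv[f"k:{lab}"])
            push(index._map[(g, "a")], sv["a"])
            push(index._map[(g, "b")], sv["b"])
        elif spec.variant == "polytomous":
            # dichotomize every item at its top category, run the closed form,
            # then match each cumulative marginal to a Beta moment
            top_pats = [tuple(1 if v == J else 0 for v, J in zip(p, gt.n_categories))
                        for p in gt.patterns]
            dich = _aggregate(top_pats, gt.counts, spec.item_labels)
            ref = None
            for i, lab in enumerate(spec.item_labels):
                if f"kappa:{lab}:1" in spec.fixed:
                    ref = i
                    break
            try:
                sv = start_values(dich, ref_item=ref)
                a0, b0 = sv["a"], sv["b"]
            except ValueError:
                a0 = b0 = 1.0
            dist0 = TraitDistribution(max(a0, 1e-3), max(b0, 1e-3))
            push(index._map[(g, "a")], dist0.a)
            push(index._map[(g, "b")], dist0.b)
            for i, (lab, J) in enumerate(zip(spec.item_labels, spec.n_categories)):
                # cumulative shares of the top m categories, m = 1..J-1
                kappa_prev = None
                for m in range(1, J):
                    share = sum(
                        c for pat, c in zip(gt.patterns, gt.counts) if pat[i] >= J - m + 1
                    ) / gt.N
                    kappa = _solve_exponent(dist0, share)
                    if kappa_prev is not None:
                        kappa = min(kappa, 0.95 * kappa_prev)  # keep descending
                    if m == 1:
                        push(index._map[(g, f"kappa:{lab}:1")], kappa)
                    else:
                        ratio = min(max(kappa / kappa_prev, 1e-4), 1.0 - 1e-4)
                        push(index._map[(g, f"r:{lab}:{m}")], ratio)
                    kappa_prev = kappa
        else:  # unfolding: neutral trait, unit hardnesses, mid-range alpha
            push(index._map[(g, "a")], 1.0)
            push(index._map[(g, "b")], 1.0)
            for lab in spec.item_labels:
                push(index._map[(g, f"k:{lab}")], 1.0)
                push(index._map[(g, f"alpha:{lab}")], 3.0)

    return {sid: float(np.mean(vs)) for sid, vs in acc.items()}


def _aggregate(patterns, counts, labels) -> PatternTable:
    agg: dict[tuple[int, ...], float] = {}
    for p, c in zip(patterns, counts):
        agg[p] = agg.get(p, 0.0) + float(c)
    return PatternTable(
        patterns=list(agg.keys()),
        counts=np.array(list(agg.values())),
        item_labels=labels,
        n_categories=(2,) * len(labels),
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _group_pattern_prob(params, dist, pattern, variant: str) -> float:
    if variant == "dichotomous":
        return pattern_prob(pattern, params, dist)
    if variant == "polytomous":
        return poly_pattern_prob(pattern, params, dist)
    return unfolding_pattern_prob(pattern, params)


def _nll(theta: np.ndarray, index: ParameterIndex, table: PatternTable) -> float:
    spec = index.spec
    total = 0.0
    try:
        for g in spec.groups:
            params, dist = index.group_params(theta, g)
            gt = table.group_table(g)
            for pat, c in zip(gt.patterns, gt.counts):
                if c == 0:
                    continue
                try:
                    p = _group_pattern_prob(params, dist, pat, spec.variant)
                except NumericalInstabilityError:
                    p = 0.0
                total -= c * math.log(max(p, LIKELIHOOD_PROB_FLOOR))
    except (ValueError, OverflowError):
        logger.debug("penalized non-finite likelihood at theta=%s", theta)
        return 1e12
    if not math.isfinite(total):
        logger.debug("penalized non-finite likelihood at theta=%s", theta)
        return 1e12
    return total


def negative_loglik(
    theta: np.ndarray, spec: ModelSpec, table: PatternTable
) -> float:
    """Negative multinomial log-likelihood at a free-parameter vector.

    ``theta`` lives on the transformed (log / logit) scale defined by
    :class:`ParameterIndex`; probabilities are floored at 1e-300 and
    non-finite evaluations return a large penalty so line searches survive
    extreme proposals.
    """
    return _nll(np.asarray(theta, dtype=float), ParameterIndex(spec), table)


def _num_grad(f: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    for i in range(len(x)):
        step = h * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        g[i] = (f(xp) - f(xm)) / (2.0 * step)
    return g


def _num_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    steps = h * (1.0 + np.abs(x))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / steps[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return H


# ---------------------------------------------------------------------------
# Fit driver
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    """Tunable knobs for :func:`fit_ml`.

    method : "bfgs" (default quasi-Newton) or "cg" (Polak–Ribiere conjugate
        gradients) for the gradient-based stage; a Nelder–Mead polish always
        follows and the better optimum is kept.
    """

    method: str = "bfgs"
    seed: int = 0
    max_restarts: int = 5
    gtol: float = 1e-6
    ftol: float = 1e-9
    compute_se: bool = True
    start: Mapping[str, float] | None = None  # natural slot values


@dataclass
class FitResult:
    """Converged (or best-effort) ML fit of an EBE model."""

    spec: ModelSpec
    estimates: dict[str, dict[str, float]]
    standard_errors: dict[str, dict[str, float | None]]
    loglik: float
    lr_chisq: float
    df: int
    p_value: float
    bic: float
    converged: bool
    n_free: int
    start_values: dict[str, float]
    theta: np.ndarray
    data_hash: str
    n_obs: float
    message: str = ""

    def group_model(self, group: str = "all"):
        """(item parameters object, TraitDistribution) for one group."""
        return ParameterIndex(self.spec).group_params(self.theta, group)


def data_fingerprint(table: PatternTable) -> str:
    rows = sorted(
        (table.groups[i] if table.groups else "", table.patterns[i], float(table.counts[i]))
        for i in range(len(table.patterns))
    )
    payload = repr((table.item_labels, table.n_categories, rows)).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def fit_ml(
    table: PatternTable,
    spec: ModelSpec,
    options: FitOptions | None = None,
) -> FitResult:
    """Full-information ML fit of an EBE model specification.

    Minimizes the negative multinomial log-likelihood from closed-form start
    values using a gradient-based search (BFGS by default) followed by a
    Nelder–Mead polish, keeping the better optimum.  Convergence requires the
    inter-stage improvement to fall below ``ftol`` and the numerical gradient
    infinity-norm below a sample-size-scaled ``gtol``; on failure up to
    ``max_restarts`` jittered restarts are attempted and the best fit is
    returned with ``converged=False`` and a warning if none succeeds.
    """
    opts = options or FitOptions()
    index = ParameterIndex(spec)
    index.check_identified(table)
    missing = set(spec.groups) - set(table.group_labels)
    if missing:
        raise ValueError(f"spec groups {missing} not present in the data")

    starts = dict(_default_starts(index, table))
    if opts.start:
        starts.update(opts.start)
    theta0 = index.pack(starts)
    logger.info(
        "fit_ml: variant=%s groups=%s n_free=%d start=%s",
        spec.variant, spec.groups, index.n_free,
        {s.id: round(starts[s.id], 4) for s in index.free_slots},
    )

    f = lambda th: _nll(th, index, table)
    rng = np.random.default_rng(opts.seed)
    method = {"bfgs": "BFGS", "cg": "CG"}[opts.method]
    # gradient tolerance scaled by N: the loglik is a sum over N observations
    gtol_eff = opts.gtol * max(table.N, 1.0)

    best_theta, best_val, converged = None, np.inf, False
    attempt_theta0 = theta0.copy()
    for attempt in range(opts.max_restarts + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = optimize.minimize(f, attempt_theta0, method=method)
            r2 = optimize.minimize(
                f, r1.x, method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12,
                         "maxiter": 20000, "maxfev": 20000},
            )
            stage_vals = [r1.fun, r2.fun]
            r = r2 if r2.fun <= r1.fun else r1
            # one more quasi-Newton pass from the polished point
            r3 = optimize.minimize(f, r.x, method=method)
            if r3.fun < r.fun:
                r = r3
            stage_vals.append(r.fun)
        if r.fun < best_val:
            best_val, best_theta = r.fun, r.x.copy()
        grad = _num_grad(f, r.x, h=1e-6)
        dval = abs(stage_vals[-2] - stage_vals[-1])
        ok = dval < opts.ftol * (1.0 + abs(r.fun)) and np.max(np.abs(grad)) < gtol_eff
        logger.info(
            "fit_ml attempt %d: nll=%.6f |grad|_inf=%.3g dval=%.3g converged=%s",
            attempt, r.fun, np.max(np.abs(grad)), dval, ok,
        )
        if ok and r.fun <= best_val:
            converged = True
            break
        attempt_theta0 = theta0 + rng.normal(0.0, 0.3, size=len(theta0))
    if not converged:
        warnings.warn(
            f"fit_ml did not meet convergence tolerances after "
            f"{opts.max_restarts + 1} attempts; returning best point found"
        )

    theta = best_theta
    loglik = -best_val
    estimates = index.natural_estimates(theta)

    l2, df, p, bic = _fit_stats(index, theta, table)
    ses = (
        _standard_errors(index, theta, table)
        if opts.compute_se
        else {g: {n: None for n in d} for g, d in estimates.items()}
    )
    return FitResult(
        spec=spec,
        estimates=estimates,
        standard_errors=ses,
        loglik=loglik,
        lr_chisq=l2,
        df=df,
        p_value=p,
        bic=bic,
        converged=converged,
        n_free=index.n_free,
        start_values={s.id: starts[s.id] for s in index.free_slots},
        theta=np.asarray(theta),
        data_hash=data_fingerprint(table),
        n_obs=table.N,
    )


# ---------------------------------------------------------------------------
# Fit statistics and standard errors
# ---------------------------------------------------------------------------


def _fit_stats(index: ParameterIndex, theta, table: PatternTable):
    spec = index.spec
    l2 = 0.0
    for g in spec.groups:
        params, dist = index.group_params(theta, g)
        gt = table.group_table(g)
        for pat, c in zip(gt.patterns, gt.counts):
            if c <= 0:
                continue
            p = _group_pattern_prob(params, dist, pat, spec.variant)
            l2 += 2.0 * c * math.log(c / (gt.N * p))
    cells = table.n_cells
    df = len(spec.groups) * (cells - 1) - index.n_free
    p_value = float(chi2.sf(l2, df)) if df > 0 else float("nan")
    bic = l2 - df * math.log(table.N)
    return l2, df, p_value, bic


def lr_fit_stats(fit: FitResult, table: PatternTable) -> tuple[float, int, float, float]:
    """(L^2, df, p, BIC) of a fitted model against the saturated multinomial.

    L^2 = 2 sum_{cells with count>0} obs*log(obs/expected); df counts all
    possible cells per group minus one, minus the number of free parameters;
    BIC is Raftery's L^2 - df*ln(N) with N pooled across groups.
    """
    index = ParameterIndex(fit.spec)
    return _fit_stats(index, fit.theta, table)


def _standard_errors(index: ParameterIndex, theta, table: PatternTable):
    """Observed-information SEs on the natural scale via the delta method."""
    spec = index.spec
    estimates = index.natural_estimates(theta)
    out: dict[str, dict[str, float | None]] = {
        g: {n: None for n in d} for g, d in estimates.items()
    }
    if index.n_free == 0:
        return out
    f = lambda th: _nll(th, index, table)
    H = _num_hessian(f, np.asarray(theta, dtype=float))
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        warnings.warn("observed information is singular; standard errors unavailable")
        return out
    if np.any(np.diag(cov) <= 0):
        warnings.warn(
            "observed information is not positive definite (boundary or flat "
            "likelihood); standard errors reported as missing"
        )
        return out

    # Jacobian of the natural parameters w.r.t. theta, by central differences
    names = [(g, n) for g in spec.groups for n in estimates[g]]

    def nat_vec(th):
        e = index.natural_estimates(th)
        return np.array([e[g][n] for g, n in names])

    th = np.asarray(theta, dtype=float)
    J = np.zeros((len(names), len(th)))
    for i in range(len(th)):
        h = 1e-6 * (1.0 + abs(th[i]))
        tp, tm = th.copy(), th.copy()
        tp[i] += h
        tm[i] -= h
        J[:, i] = (nat_vec(tp) - nat_vec(tm)) / (2.0 * h)

    var = np.einsum("ij,jk,ik->i", J, cov, J)
    for (g, n), v in zip(names, var):
        if index.is_natural_fixed(g, n):
            continue
        out[g][n] = math.sqrt(v) if v > 0 else None
    return out


def standard_errors(
    fit: FitResult, spec: ModelSpec | None = None, table: PatternTable | None = None
) -> dict[str, dict[str, float | None]]:
    """Recompute observed-information standard errors at the MLE.

    Square roots of the diagonal of the inverse observed information
    (central-difference Hessian of the negative log-likelihood), propagated
    to the natural parameter scale by the delta method.  Fixed parameters get
    no SE.
    """
    if table is None:
        raise ValueError("standard_errors needs the fitted table")
    index = ParameterIndex(spec or fit.spec)
    return _standard_errors(index, fit.theta, table)


def _constraint_relation(spec: ModelSpec, index: ParameterIndex):
    """Partition of (group, natural-parameter) pairs plus fixed assignments."""
    fixed: dict[tuple[str, str], float] = {}
    classes: dict[str, set[tuple[str, str]]] = {}
    for (g, key), sid in index._map.items():
        slot = index._slots[sid]
        if slot.fixed is not None:
            fixed[(g, key)] = slot.fixed
        else:
            classes.setdefault(sid, set()).add((g, key))
    return fixed, list(classes.values())


def nested_lr_test(
    fit_general: FitResult, fit_restricted: FitResult
) -> tuple[float, int, float]:
    """Likelihood-ratio test of a restricted model against a nesting general one.

    Returns (delta L^2, delta df, p).  The restricted spec must impose every
    constraint of the general spec (same fixed values; every parameter pair
    equated in the general spec also equated or fixed in the restricted one),
    and both fits must come from the same data.
    """
    if fit_general.data_hash != fit_restricted.data_hash:
        raise ValueError("fits come from different data")
    gi = ParameterIndex(fit_general.spec)
    ri = ParameterIndex(fit_restricted.spec)
    g_fixed, g_classes = _constraint_relation(fit_general.spec, gi)
    r_fixed, r_classes = _constraint_relation(fit_restricted.spec, ri)
    for key, val in g_fixed.items():
        if r_fixed.get(key) != val:
            raise ValueError(f"restricted model frees or changes fixed parameter {key}")

    def r_class_of(key):
        if key in r_fixed:
            return ("fixed", r_fixed[key])
        for i, cls in enumerate(r_classes):
            if key in cls:
                return ("class", i)
        raise ValueError(f"parameter {key} absent from restricted model")

    for cls in g_classes:
        tags = {r_class_of(k) for k in cls}
        if len(tags) > 1:
            raise ValueError(
                f"models are not nested: parameters {sorted(cls)} are equated in "
                "the general model but not in the restricted one"
            )
    delta = fit_restricted.lr_chisq - fit_general.lr_chisq
    ddf = fit_restricted.df - fit_general.df
    if ddf < 0:
        raise ValueError("restricted model has fewer df than the general model")
    p = float(chi2.sf(delta, ddf)) if ddf > 0 else float("nan")
    return delta, ddf, p
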