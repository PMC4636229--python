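"""Shared fixtures and independent quadrature oracles.

The oracles integrate the conditional pattern probability against the Beta
density numerically (adaptive quadrature / high-order Gauss–Legendre), fully
independent of the signed-moment expansion they are used to check.
"""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

import ebeirt as eb
from ebeirt.polytomous import category_terms


# ---------------------------------------------------------------------------
# Quadrature oracles
# ---------------------------------------------------------------------------


def gauss_legendre_moment(a: float, b: float, k: float, nodes: int = 512) -> float:
    """E[y^k] under Beta(a,b) by fixed-order Gauss-Legendre quadrature."""
    x, w = np.polynomial.legendre.leggauss(nodes)
    y = 0.5 * (x + 1.0)  # map [-1,1] -> [0,1]
    return 0.5 * np.sum(w * y**k * beta_dist.pdf(y, a, b))


def _quad_expect(cond_prob, dist: eb.TraitDistribution, moment: int = 0) -> float:
    """Integral of y^moment * cond_prob(y) * beta_pdf(y) over (0,1)."""

    def integrand(y):
        return y**moment * cond_prob(y) * beta_dist.pdf(y, dist.a, dist.b)

    val, _ = quad(integrand, 0.0, 1.0, limit=400, epsabs=1e-13, epsrel=1e-12)
    return val


def quad_pattern_prob(x, items, dist: eb.TraitDistribution, moment: int = 0) -> float:
    """Oracle Pr[x] (or the +moment posterior numerator) for any variant."""
    x = tuple(x)

    if isinstance(items, eb.ItemParams):
        def cond(y):
            p = 1.0
            for xi, k in zip(x, items.k):
                pi = y**k
                p *= pi if xi == 1 else 1.0 - pi
            return p
    elif isinstance(items, eb.ThresholdSet):
        def cond(y):
            p = 1.0
            for j, kappa in zip(x, items.thresholds):
                p *= sum(c * y**e for c, e in category_terms(j, kappa))
            return p
    elif isinstance(items, eb.UnfoldingParams):
        def cond(y):
            p = 1.0
            for xi, k, al in zip(x, items.k, items.alpha):
                pi = al * y**k * (1.0 - y**k)
                p *= pi if xi == 1 else 1.0 - pi
            return p
        if dist is None:
            dist = items.dist
    else:
        raise TypeError(type(items))
    return _quad_expect(cond, dist, moment)


@pytest.fixture(scope="session")
def oracle():
    return quad_pattern_prob


@pytest.fixture(scope="session")
def gl_moment():
    return gauss_legendre_moment


# ---------------------------------------------------------------------------
# Data and cached fits (session-scoped: fitting is deterministic)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def army():
    return eb.load_fixture("army")


@pytest.fixture(scope="session")
def italian():
    return eb.load_fixture("italian")


@pytest.fixture(scope="session")
def alcohol():
    return eb.load_fixture("alcohol")


@pytest.fixture(scope="session")
def army_fit(army):
    spec = eb.ModelSpec.from_table(army, anchor="D")
    return eb.fit_ml(army, spec)


@pytest.fixture(scope="session")
def alcohol_fit(alcohol):
    spec = eb.ModelSpec.from_table(alcohol, variant="polytomous", anchor="health")
    return eb.fit_ml(alcohol, spec)


@pytest.fixture(scope="session")
def italian_ladder(italian):
    """The six nested two-group models, anchored on item 3 in both groups."""

    def spec(shared):
        return eb.ModelSpec.from_table(italian, fixed={"k:item3": 1.0}, shared=shared)

    shared_sets = {
        1: [],
        2: ["k:item1", "k:item2", "k:item4"],
        3: ["a", "b"],
        4: ["a", "b", "k:item2"],
        5: ["a", "b", "k:item2", "k:item4"],
        6: ["a", "b", "k:item1", "k:item2", "k:item4"],
    }
    opts = eb.FitOptions(compute_se=False)
    return {m: eb.fit_ml(italian, spec(s), opts) for m, s in shared_sets.items()}


@pytest.fixture(scope="session")
def army_anchor_fits(army):
    """Refits of the Army table under each of the four anchor normalizations."""
    opts = eb.FitOptions(compute_se=False)
    return {
        anchor: eb.fit_ml(army, eb.ModelSpec.from_table(army, anchor=anchor), opts)
        for anchor in army.item_labels
    }


def random_dichotomous_params(rng, M=None):
    """Random valid (ItemParams, TraitDistribution) draws for oracle checks."""
    if M is None:
        M = int(rng.integers(1, 7))
    k = rng.uniform(0.05, 20.0, size=M)
    a, b = rng.uniform(0.2, 20.0, size=2)
    return eb.ItemParams(k), eb.TraitDistribution(a, b)


@pytest.fixture(scope="session")
def random_params():
    return random_dichotomous_params
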