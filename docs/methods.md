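# Methods

## Model family

All three variants share one latent structure: each respondent carries a
trait value *y* ∈ (0, 1), distributed Beta(a, b) in the population
(densities per group in multi-group fits), and item responses are independent
given *y*.

**Dichotomous.** Pr[x_i = 1 | y] = y^{k_i} with hardness k_i > 0.  The trait
is the probability of endorsing a standardized (k = 1) item; harder items
(larger k) are endorsed less at every trait value.  On the unbounded scale
ξ = −log(−log y), χ = log k the response function is the double exponential
exp(−exp(−(ξ − χ))).  Note that it passes probability one-half at
ξ − χ = −log(log 2) ≈ **+0.3665** (some accounts quote this offset with a
negative sign; the algebra gives the positive value, which is what the code
implements — the function has no symmetry point at ξ = χ).

**Ordered categories.** For J ordered categories, cumulative probabilities
follow the dichotomous form: Pr[x_i in the top m categories | y] = y^{κ_{i,m}}
with κ_{i,1} > κ_{i,2} > … > κ_{i,J−1} > 0, so that the cumulative
probability grows as the cut moves down.  Category probabilities are
differences of adjacent cumulatives; each interior category's curve is
single-peaked in y with peaks ordered by category.  We index thresholds from
the **top** category downward — with descending exponents — because that is
the only direction compatible with valid cumulative probabilities (y < 1
makes y^κ decrease in κ); published notation sometimes writes the inequality
in ascending order, which we treat as an index-direction slip.  Collapsing
adjacent categories exactly removes the interior threshold and sums the
category probabilities (joining assumption), and dichotomizing at any cut
reproduces the dichotomous model with k equal to that cut's exponent
(ξ-equivalence).

**Unfolding.** Pr[x_i = 1 | y] = α_i y^{k_i}(1 − y^{k_i}), single-peaked
with maximum α_i/4 at y = 0.5^{1/k_i}.  With α = 4 the peak response
probability is exactly 1.  α > 4 produces invalid probabilities near the peak
and is allowed only behind an explicit override (and never in simulation).
The variant's unbounded trait map is ξ = −log(−2 log y), which puts the peak
at ξ = χ.

## Exact pattern probabilities

Each item contributes a short signed list of (coefficient, exponent) terms to
Pr[x_i | y] — one term for a positive dichotomous response, two for a
negative one or an extreme category, three for a negative unfolding response.
The product over items expands into at most 2^M (3^M for unfolding) Beta
power moments E[y^s] = B(a+s, b)/B(a, b), each evaluated on the log-gamma
scale.  This is the inclusion–exclusion representation over the negatively
answered item set; the polytomous and unfolding expansions are the same
machinery with different per-item term lists.

The expansion is alternating, so the sum is accumulated with `math.fsum`
(exact, round-off-free compensated summation).  If cancellation still drives
a total nonpositive — possible only at extreme parameters — a
`NumericalInstabilityError` names the offending pattern.  Inside likelihood
evaluation only, probabilities are floored at 1e-300 before logging so that
line searches survive wild proposals; the public probability API never
clamps.  Exhaustive enumeration is refused above M = 20 items (warning above
12); unfolding patterns are capped at 12 items.

Posterior (EAP) scores reuse the identical expansion: E[y|x] and E[y²|x] are
ratios of the same signed sums with every exponent shifted by 1 or 2.  No
quadrature is used anywhere in the package; adaptive quadrature of the
conditional likelihood against the Beta density serves as the independent
oracle in the test suite (tolerance 1e-8 on probabilities and posterior
moments; fixed-order Gauss–Legendre is additionally used for single moments,
where its accuracy is limited to ~1e-10 by the density's algebraic endpoint
behaviour).

## Identification and normalization

One item-side parameter must be fixed per trait scale — conventionally one
hardness (or one top threshold) set to 1.  This holds for the unfolding
variant too: fixing α does **not** pin the hardness scale, and measured
likelihood surfaces show a near-flat ridge along joint rescalings of all k
(because a power of a Beta variable is nearly, but not exactly, Beta).  For
the same reason the fit statistic is only *approximately* invariant to which
item anchors the scale: on the bundled Army table the converged L² ranges
over ≈0.9 chi-square units across the four anchor choices, while the
estimates obey the rescaling relation k_i^{(j)} ≈ k_i^{(h)}/k_j^{(h)} to
about 1%.  Anchor choice therefore affects reported, not intrinsic,
quantities, and every fit logs it.  The b = 1 submodel is underidentified
without an additional constraint; with one, the fitted marginals obey
Pr[x_i=1] = a/(a+k_i) and k_i/a = (1−P)/P exactly.

## Estimation

The multinomial log-likelihood over observed pattern counts is maximized
jointly in all free parameters (item and trait parameters are not separable
in this family).  Free positive parameters are optimized as logs; descending
threshold sequences are parameterized as a top exponent (log scale) times
cumulative ratios in (0, 1) (logit scale), so every optimizer iterate is
correctly ordered; free unfolding α uses a (0, 4] scaled logit.

Start values come from a closed-form inversion of 2×2 cross-classifications
with the anchor item: each pair gives S_j = k_j/(a+b) from joint and marginal
proportions, a single positive root Θ = a + b follows from a bracketed
(grid-scan + Brent) root search on the anchor marginal equation, admissible
roots are averaged, and a = Θ·P_anchor, k_j = Θ·S_j.  Pairs with nonpositive
association are excluded with a warning and seeded from marginal odds.
Polytomous fits dichotomize at the top category for (a, b) and then match
each cumulative marginal to a Beta moment; unfolding fits start from neutral
values (k = 1, a = b = 1) and rely on restarts.  On an exact population table
the inversion recovers Θ = a + b to root-solver tolerance.

Optimization is BFGS with numerical gradients (Polak–Ribière conjugate
gradients available via `FitOptions(method="cg")`), followed by a Nelder–Mead
simplex polish and a final quasi-Newton pass, keeping the best point.
Convergence requires the inter-stage improvement below 1e-9·(1+|loglik|) and
the gradient infinity-norm below 1e-6·N (the likelihood scales with the
sample size); up to 5 jittered restarts (seeded, N(0, 0.3²) on the
transformed scale) are attempted before returning `converged=False` with a
warning.

Standard errors are square roots of the diagonal of the inverse observed
information — a central-difference Hessian of the negative log-likelihood in
the free (transformed) parameters — propagated to the natural scale by the
delta method.  Fixed parameters get no SE; a non-positive-definite
information matrix yields missing SEs with a warning.  Because hardnesses are
strictly positive, these SEs should not be read as symmetric confidence
intervals; nested likelihood-ratio tests are the preferred way to compare
constrained and unconstrained parameters.

## Fit statistics

L² = 2 Σ obs·log(obs/expected) over cells with positive counts, against the
saturated multinomial; df = Σ_g (cells_g − 1) − n_free counts **all**
possible cells per group (zero-count cells contribute nothing to L² but are
counted in df); p is the upper chi-square tail; BIC = L² − df·ln N with N
pooled across groups (the single-group convention extended — a documented
choice).  `nested_lr_test` verifies structural nesting (every fixed and
equality constraint of the general model is implied by the restricted one)
before differencing.

## Synthetic data

`simulate` draws one trait per respondent from the group's Beta and then
items independently in index order from a single seeded stream, so identical
seed and configuration reproduce the table exactly.  Default study conditions
in the tests mirror the bundled data: short scales (M ≤ 4, J ≤ 4), samples
in the 500–2000 range for realism and N = 20000 for parameter-recovery
checks, with true parameters set to the fitted values of the bundled tables.
`population_table` emits exact pattern probabilities as real-valued counts
for noise-free oracle tests.  The generator emulates conditional independence
and simple random sampling only — no item nonresponse, clustering, sampling
weights or response-order effects — so passing recovery tests speak to the
estimator, not to robustness against those features of real surveys.

## Known limitations

* Cost grows exponentially in the number of items (2^M terms per pattern,
  2^M patterns); the family targets short scales, not long tests.
* The anchor choice moves L² by a small but nonzero amount (see above);
  reported hardnesses are relative to the anchor.
* Multi-group BIC uses pooled N; other conventions exist.
* SEs from observed information are asymptotic and asymmetric-parameter
  caveats apply (see Estimation).
* No missing-data handling; tables must be complete cross-classifications of
  observed patterns.
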