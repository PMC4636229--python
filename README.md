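# ebeirt — extended binomial error item response models

`ebeirt` fits a family of item response models in which the latent trait *y*
lives on (0, 1) and is itself interpretable as a probability: the chance of
endorsing a standardized item.  The dichotomous response function is

    Pr[x_i = 1 | y] = y^{k_i},      k_i > 0,

an extension of the classic binomial error (beta-binomial) strong true-score
model to items of unequal difficulty, with the trait given a two-parameter
Beta(a, b) distribution.  The same construction yields an ordered-category
model through cumulative thresholds, Pr[x_i ≥ j | y] = y^{κ_{i,j}}, and a
single-peaked (ideal-point / unfolding) model, Pr[x_i = 1 | y] =
α_i y^{k_i}(1 − y^{k_i}).

The pattern probability needed for full-information maximum likelihood has an
exact closed form: every response pattern expands by inclusion–exclusion into
a signed sum of Beta power moments,

    Pr[x] = Σ_{A ⊆ I(x)} (−1)^{|A|} E[y^{Σ_{i ∈ A ∪ C(x)} k_i}],
    E[y^k] = Γ(a+b) Γ(a+k) / (Γ(a) Γ(a+b+k)),

where C(x) and I(x) are the positively and negatively answered item sets.  No
numerical integration is ever used in estimation or scoring; quadrature
appears only as an independent oracle in the test suite.

The package is aimed at analyses of short attitude/behaviour scales from
surveys and randomized question-wording experiments, where the interesting
questions are about the response process and the *distribution* of the trait:
it supports multi-group fits with arbitrary fixed/shared parameter
constraints (measurement-invariance ladders tested by nested likelihood-ratio
chi-squares and compared by Raftery's BIC = L² − df·ln N), posterior (EAP)
scoring of response patterns, and synthetic data generation for all three
variants.

## Worked example

Three published cross-classification tables ship with the package.  The
classic four-item Army attitude data (N = 1000) with item D as the anchor
(k_D = 1):

```python
import ebeirt as eb

army = eb.load_fixture("army")
spec = eb.ModelSpec.from_table(army, anchor="D")
fit = eb.fit_ml(army, spec)
print(f"L^2 = {fit.lr_chisq:.3f}  df = {fit.df}  p = {fit.p_value:.3f}  BIC = {fit.bic:.2f}")
for name, v in fit.estimates["all"].items():
    se = fit.standard_errors["all"][name]
    print(f"  {name:5s} = {v:.4f}" + (f"  (SE {se:.4f})" if se else "  (fixed)"))
s = eb.posterior_score((1, 0, 1, 0), *fit.group_model("all"))
print(f"EAP for pattern 1010: mean = {s.mean:.4f}, sd = {s.variance**0.5:.4f}, Pr = {s.pattern_prob:.4f}")
```

prints

```
L^2 = 17.422  df = 10  p = 0.066  BIC = -51.66
  k:A   = 4.0878  (SE 0.3126)
  k:B   = 3.4004  (SE 0.2538)
  k:C   = 2.5674  (SE 0.1876)
  k:D   = 1.0000  (fixed)
  a     = 3.0224  (SE 0.3379)
  b     = 1.7174  (SE 0.1627)
EAP for pattern 1010: mean = 0.7395, sd = 0.1135, Pr = 0.0123
```

The model reproduces the 16 observed pattern frequencies acceptably
(likelihood-ratio chi-square 17.42 on 10 df, p = .066) and, being more
parsimonious than a saturated or Rasch-type alternative, earns a strongly
negative BIC.  Items A–C are progressively easier to endorse than the anchor
D; the Beta(3.02, 1.72) trait distribution puts most respondents above 0.5.
The EAP score for pattern 1010 shows the posterior trait estimate and its
precision for that answer combination.

The same interface drives the other variants and multi-group constraint
ladders, e.g.

```python
italian = eb.load_fixture("italian")      # two randomized conditions
m1 = eb.fit_ml(italian, eb.ModelSpec.from_table(italian, fixed={"k:item3": 1.0}))
m3 = eb.fit_ml(italian, eb.ModelSpec.from_table(italian, fixed={"k:item3": 1.0},
                                                shared=["a", "b"]))
delta, ddf, p = eb.nested_lr_test(m1, m3)  # test of equal trait distributions
```

A command-line interface mirrors the library:

```bash
ebeirt fixtures export army --out army.tsv
ebeirt fit --data army.tsv --anchor D --out fit.json
ebeirt score --data army.tsv --fit fit.json --out scores.tsv
ebeirt simulate --spec truth.json --n 5000 --seed 42 --out sim.tsv
ebeirt compare fit1.json fit2.json
```

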