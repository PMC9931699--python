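# citebest

Robust Bayesian and rank-based comparison of citation counts between groups
of publications — built for the question of whether papers with reproducible
computational models are cited more than papers with non-reproducible ones.

Citation counts are heavy-tailed: a handful of highly cited papers can
dominate a classical t test. `citebest` therefore implements the BEST
("Bayesian estimation supersedes the t test") approach: each group *g* of
citation counts is modelled as i.i.d. draws from a location-scale Student-t
distribution

> x ~ t(μ_g, σ_g, ν)

with an individual location μ_g and scale σ_g per group and a single shape
(normality) parameter ν shared by all groups. Small ν yields heavy tails
that absorb outliers; ν → ∞ recovers the normal model. Priors are derived
from the pooled data: μ_g ~ Normal(M, S) with M the pooled mean and
S = 10 × pooled SD, σ_g ~ Uniform(SD/100, 100 × SD), and
ν = 1 + Exponential(mean 29); a sensitivity mode widens S and the σ bounds
by a further factor of 100 to check that the priors carry no weight.

Decisions are read off the posterior predictive distributions of

* the difference of means μ₁ − μ₂,
* the difference of standard deviations σ₁ − σ₂,
* Cohen's d computed per posterior draw with the unequal-n pooled SD
  σ_pooled = √(((n₁−1)σ₁² + (n₂−1)σ₂²)/(n₁+n₂−2)),

using the 95% highest-density interval (HDI): the hypothesis of equal means
is **rejected** when the HDI of μ₁ − μ₂ lies entirely above or below zero,
**accepted** when the effect-size HDI lies entirely inside the region of
practical equivalence (ROPE, default d ∈ (−0.2, 0.2)), and left
**undecided** otherwise. The ROPE is only ever used to accept the null,
never to widen rejection. Multi-group comparisons share one ν and report a
pairwise matrix of credibilities P(μ_i − μ_j > 0).

A frequentist companion is included: the Mann-Whitney U statistic from its
pairwise-score definition U = Σᵢ Σⱼ S(Xᵢ, Yⱼ) with S = 0/½/1 for
X > Y / X = Y / X < Y (exact permutation p-values for small samples, a
tie-corrected normal approximation otherwise), gated by a Shapiro-Wilk
normality test, plus a QQ-regression fit of the t family with a
Kolmogorov-Smirnov goodness-of-fit check.

The bibliometric curation layer averages citation counts over Scopus, Web
of Science and Google Scholar, imputes counts missing from the two
restrictive databases as 62.87% of the Google Scholar count, deduplicates
papers, filters by publication period, and can normalize citations by the
journal impact factor (JIF) averaged over 2014–2021. A synthetic study
generator emulates all of this structure so the whole pipeline is testable
without any external data.

## Worked example

```python
from citebest import *

records, truth = generate_study(SyntheticStudyConfig(seed=5))
groups, _ = curate(records, [Group.REPRODUCIBLE, Group.NON_REPRODUCIBLE],
                   CurationConfig())
spec = ModelSpec(groups=tuple(groups), prior=pooled_prior_spec(groups))
trace = sample_posterior(spec, draws=20_000, chains=4, seed=5)
print(summarize_comparison(trace, 0, 1))
```

prints (reformatted):

```
n1=111, n2=76
mean diff  3.17  95% HDI (0.71, 5.68)  P(>0) = 99.4%
effect size 0.39  95% HDI (0.08, 0.71)
decision: REJECT_H0_GROUP1_HIGHER
max PSRF 1.0007, min ESS 8929
Mann-Whitney U = 3308.5, p = 0.0123
```

The synthetic reproducible group was generated 3.4 citations above the
non-reproducible one; the posterior mean difference of 3.17 with an HDI
above zero recovers that shift and rejects equal means, with an effect size
of about 0.4 pooled standard deviations. PSRF ≈ 1 and a large effective
sample size confirm the chains converged and mixed.

The same analyses are available from the shell:

```sh
citebest simulate --seed 5 --out study.csv
citebest compare --table study.csv --seed 5 --outdir results/
citebest multicompare --table study.csv --seed 5 --outdir results/
citebest freq study.csv --period 2013 2020
```

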