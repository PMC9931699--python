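# Methods

## Model

Each group *g* = 1..G of analysis values (citation counts, or citation
counts divided by the journal impact factor) is modelled as independent
draws from the location-scale Student-t distribution t(μ_g, σ_g, ν). The
shape parameter ν is shared across groups: it encodes how heavy-tailed
citation data are globally, while μ_g and σ_g capture group-specific level
and spread. Independence of papers is assumed, so the likelihood factorizes
over observations. The t family is checked against the data by a
QQ-regression fit followed by a Kolmogorov-Smirnov test
(`ranktests.nct_fit_check`).

Priors are derived from the pooled (concatenated) data so that they cover
the data's order of magnitude without preferring either group:

| parameter | prior | default | sensitivity mode |
|---|---|---|---|
| μ_g | Normal(M, S) | M = pooled mean, S = 10 × pooled SD | S = 1000 × SD |
| σ_g | Uniform(L, H) | L = SD/100, H = 100 × SD | L = SD/1000, H = 1000 × SD |
| ν | offset + Exponential(mean m) | offset = 1, m = 29 | unchanged |

Pooled SD uses the n−1 denominator. The ν prior follows the original BEST
convention (mean ≈ 30 balances near-normal and heavy-tailed regimes, the
offset keeps the first moment of the likelihood finite); both offset and
mean are configurable on `PriorSpec`. Identical group data (pooled SD = 0)
is rejected rather than fitted.

## Sampling

The posterior over (μ_1..μ_G, σ_1..σ_G, ν) is explored with a
model-specific slice-sampling-within-Gibbs kernel: one sweep updates each
scalar parameter in turn by univariate slice sampling (stepping-out and
shrinkage), with ν updated as η = log(ν − offset) including the Jacobian.
Slice widths are fixed per run from data-scale estimates (≈ 4 standard
errors for μ_g and σ_g, 1.0 for η) and never depend on the coordinate's
current value, preserving detailed balance; stepping-out is capped at 50
expansions and shrinkage at 100 proposals per update. The kernel is
rejection-free and requires no step-size tuning, and for this
low-dimensional unimodal posterior mixes nearly i.i.d. (typical bulk ESS is
40–90% of the retained draws).

`draws` counts total retained sweeps across all chains (the default
100,000 over 4 chains stores 25,000 per chain); each chain first discards
1000 warm-up sweeps (configurable). Chains are seeded via
`numpy.random.SeedSequence.spawn`, so a single integer seed makes the whole
trace reproducible, and are initialized overdispersed around data
estimates. Fewer than 2 chains or fewer than 1000 total draws are refused.

Diagnostics follow the Bayesian analysis reporting guidelines: split-chain
R-hat (PSRF) and bulk ESS per scalar parameter via arviz, plus prior and
posterior predictive checks that simulate replicate datasets of the
observed group sizes and locate each observed group mean and SD within the
replicate distribution.

## Decision quantities

Per posterior draw the package computes μ₁ − μ₂, σ₁ − σ₂, and Cohen's d
with the unequal-n pooled SD
σ_pooled = √(((n₁−1)σ₁² + (n₂−1)σ₂²)/(n₁+n₂−2)), giving full posterior
distributions of all three; reported point values are posterior means.
HDIs are computed as the shortest window of ⌈mass·n⌉ consecutive order
statistics — valid for unimodal samples, which these marginals are;
multimodality is not detected. The decision rule: reject equal means when
the 95% HDI of μ₁ − μ₂ excludes zero (on either side); otherwise accept
when the effect-size HDI lies inside the ROPE (−0.2, 0.2), with inclusive
bounds; otherwise undecided. Draws exactly at zero count as "not above
zero" in credibility masses (a measure-zero tie-break). Pairwise
multi-group comparisons are reported without multiplicity adjustment —
shrinkage through the shared-ν model structure takes that role.

Multi-period analyses fit one joint shared-ν model over every
(period × group) dataset, so the pairwise credibility matrix comes from a
single coherent posterior; the per-period two-group summaries are fitted
per period as in the single-period analysis.

## Frequentist companion

The Mann-Whitney U statistic is the double sum of the pairwise score
S = 0/½/1 over all n₁·n₂ pairs; U therefore counts wins of the second
sample, and U(X,Y) + U(Y,X) = n₁·n₂ identically, ties included. Two-sided
p-values use full permutation enumeration of group labelings when the
pooled size is ≤ 12 (configurable) and otherwise the normal approximation
with tie correction; the continuity correction is on by default and
exposed. The Shapiro-Wilk gate delegates to scipy. The t-family
goodness-of-fit check fits ν by a bounded 1-D search (ν ∈ [0.5, 200] on the
log scale) maximizing the probability-plot correlation, reads μ and σ off
the QQ regression line, and KS-tests the sample against the fitted
distribution with parameters treated as fixed — which makes the KS p-value
conservative.

## Data curation

Citation counts are averaged over Scopus, Web of Science and Google
Scholar. A count missing from Scopus or Web of Science is imputed as the
Google Scholar count × 0.6287 (the corpus-level average ratio between the
restrictive databases and Google Scholar); the factor is configurable and
deliberately *not* re-estimated from the input data. A record missing both
restrictive sources gets two imputed values alongside the one real count.
Averages are kept as reals, since imputation produces fractional counts.
JIF normalization divides the citation average by the mean JIF over the
years available within 2014–2021 (partially covered journals use only their
available years); records with no JIF in the window are excluded from
JIF-normalized analyses only, and logged. Period filtering is inclusive on
both endpoints by publication year. Deduplication by paper identifier keeps
one record for exact duplicates and raises on conflicting duplicates.

## Synthetic data generator

The generator emulates the structure the analysis assumes: per paper a
latent citation value from the group's t(μ, σ, ν), clamped at zero and
rounded to an integer by default; three source counts with multiplicative
log-normal jitter (sd 0.05, keeping sources positively correlated as real
databases are) around levels chosen so Scopus and Web of Science average
62.87% of Google Scholar while the three-source mean equals the latent
value; independent source missingness for Scopus and Web of Science;
uniform publication years; log-normal per-year JIFs (log-mean 1.4,
log-sd 0.6, i.e. median ≈ 4).

Default group settings mirror the post-2013 citation study the package was
built around: n = 111 vs 76 papers, locations 13.4 vs 10.0 (a 3.4-citation
shift ≈ 0.4 pooled SDs), scale 8.5, shared ν = 2.5. These are deliberately
borderline-powered conditions: with tails this heavy a single realization
of n ≈ 100 per group can miss the shift, so seed-to-seed variation in the
detected difference is expected behavior, not a defect. Clamping and
rounding make the data mildly misspecified relative to the t likelihood —
exactly the situation the robust model is meant to tolerate; with locations
only ~1.5 scales above zero, truncation at zero also compresses the
realized group separation slightly. What passing tests on these data do
not show: real citation corpora have journal- and topic-level dependence,
time-varying citation accrual, and source coverage correlated with paper
visibility, none of which the generator models.

## Problem sizes in the test suite

Module tests run the sampler at 2,000–10,000 total draws with 2–4 chains;
the simulation studies use 50 repetitions at 10,000 draws (parameter
recovery, n = 200/group), 20 repetitions each for decision calibration
(null at n = 500/group, one-pooled-SD effect at n = 150/group), and
4,000-draw fits inside the calibration loops. These sizes give Monte-Carlo
error comfortably below the asserted margins while keeping the suite quick;
the library defaults remain 100,000 draws on 4 chains.

## Known limitations

* The HDI assumes unimodal marginals; it is not a general mode-finding HDI.
* The KS check after fitting parameters on the same data is conservative.
* The exact Mann-Whitney enumeration is combinatorial and only used for
  pooled n ≤ 12 by default.
* The shared-ν assumption means one group's extreme outliers influence the
  tail-weight inferred for all groups.
* Curation trusts its input table; it does not detect source-specific
  reporting errors beyond schema validation.
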