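# Methods

## Model and procedure

`callrhythm` tests, per individual, whether the circadian rhythm of
telephone-call activity is *persistent*: whether the individual's hourly
call profile resembles their own profile in an adjacent time period more
than it resembles the profiles of the other individuals in the cohort.

The observation window is partitioned into N_T ≥ 2 successive half-open
periods. Within each period and direction mode (outgoing, incoming,
total) the daily rhythm of individual *i* is the empirical distribution
f_i(t) = n_i(t)/Σ n_i(t) over the 24 hour-of-day slots [t, t+1). No
smoothing or pseudo-counts are applied, so a rhythm is undefined for an
empty period; such individuals are excluded from that mode's analysis
entirely (as focal *and* as comparator), shrinking n_comp = 2n − 2 for
everyone. This keeps the two per-period comparison vectors balanced.

Dissimilarity between rhythms is the square-root Jensen–Shannon
divergence, a bounded metric. The intra-individual dissimilarity y_i
(between *i*'s rhythms in two successive periods) is compared with the
2n − 2 inter-individual dissimilarities x_{i,j}^{T_k} (between *i* and
each j ≠ i within each period) through strict indicators
1{y_i − x > 0}; their sum N⁺ is referred to an exact
Binomial(2n − 2, q) null with q = ½ (median test), lower tail. A small
N⁺ — few strangers resemble *i* as much as *i* resembles their own past —
yields a small p-value and a persistence verdict at level α.

For N_T > 2 periods, consecutive pairwise verdicts form a binary vector v
of length N_T − 1 and a second-level exact sign test (upper tail of
Binomial(N_T − 1, ½)) assesses the trend. With short sequences this test
has little power: v = (1,1,1) gives p = 0.125, and N_T ≥ 7 periods of
uninterrupted persistence are needed to reach α = 0.05.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `q` | 0.5 | null success probability of one comparison (median test) |
| `alpha` | 0.05 | significance level of the persistence verdict |
| `log_base` | 2 | logarithm base of the divergence; rescales every dissimilarity by a common factor, so z, N⁺ and p are invariant to it (tested) |
| `bh_correct` | off | adds a Benjamini–Hochberg-adjusted p-value column per mode; the verdict still uses raw p-values, matching the per-individual reporting convention |

Numerical choices: the binomial tail is computed by exact term-by-term
summation of C(n,k) q^k (1−q)^{n−k} with exact integer coefficients and
compensated (`fsum`) accumulation — no normal approximation; p-values are
kept in full double precision and a formatter renders the conventional
3-significant-figure scientific notation. Dissimilarity ties count as
failures (strict inequality), which is conservative for persistence.
Zero rhythm bins follow 0·log(0/m) = 0; a mixture bin vanishes only where
both rhythms are zero and then contributes nothing.

## Synthetic cohorts

The generator emulates the kind of dataset this method targets: a small
cohort (default 26 individuals) observed for a year in two 182-day
periods with Poisson(300) calls per individual-period. Each individual
draws a 24-bin base profile from Dirichlet(24·c·template), where the
fixed diurnal template carries almost no mass between midnight and 6 a.m.
and c (`profile_concentration`, default 5) sets population homogeneity.
Calls then sample hours i.i.d. from the period profile, with uniform day
and minute and Bernoulli(½) direction. A fraction of individuals
(`drift_fraction`, default 0.15) *drift*: from the second period on their
profile is mixed with a freshly drawn one, (1 − s)·base + s·fresh, with
`drift_strength` s defaulting to 1 (full redraw — behaviourally unrelated
periods). All randomness flows through one seeded generator with a
documented draw order, so datasets are byte-reproducible.

What the generator does **not** emulate: social-network structure among
peers, within-day burstiness and autocorrelation, weekday/weekend or
seasonal effects, and call-volume heterogeneity between individuals. A
green parameter-recovery test therefore establishes that the statistic
recovers multinomially stable vs redrawn profiles at realistic volumes —
not that it is robust to every feature of real CDRs.

## Known limitation: the binomial null under dependence

The null N⁺ ~ Binomial(2n − 2, q) treats the 2n − 2 comparisons as
independent. They are not: every comparison shares the same y_i, and the
per-period comparisons share the focal individual's period profiles.
Conditionally on y_i, N⁺ ≈ (2n − 2)·F(y_i) where F is the distribution
of the inter-individual dissimilarities, so under a global null (every
individual's profile independently redrawn each period) N⁺ is nearly
uniform on 0..2n−2 rather than binomial: simulation at the default
cohort shape gives mean(N⁺) ≈ 25.5 (unbiased) but sd ≈ 13.6 against the
binomial 3.54, and an empirical type-I rate of ≈ 0.37 at nominal
α = 0.05 (520 individual-replicates; independent of population
homogeneity). The dedicated calibration test asserts the nominal bound
and is therefore expected to fail — it quantifies, rather than resolves,
the dependence. Practical reading: a persistence p-value is an exact
statement only under the independence idealisation; verdicts near the
threshold should be treated as descriptive, while the extreme p-values
that dominate in practice (≈ 10⁻¹⁶ … 10⁻⁷) survive any reasonable
dependence correction. Permutation-based or correlation-adjusted nulls
are out of scope.

## Design choices

- **Tail choice.** The test is one-sided lower-tail: persistence is
  evidenced by *few* successes. This is forced by the arithmetic of the
  reported reference values (e.g. N⁺ = 0 ↔ p = 0.5^50, N⁺ = 31 of 50 ↔
  p = 0.968) and is asserted in the acceptance tests.
- **Half-open conventions** for periods and hour slots give every event
  exactly one bin.
- **Local civil time** as recorded; CDR timestamps are provider-local and
  no DST normalisation is attempted.
- **Zero-duration calls are retained** by default (the event, not its
  length, carries the rhythm); durations are parsed but unused.
- **Malformed rows** are skipped with a warning by default; `--strict`
  makes them fatal.
- The **sequence-test null** Binomial(N_T − 1, ½), upper tail, mirrors
  the default q of the pairwise test; the choice is a package decision,
  not an inherited fact.
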