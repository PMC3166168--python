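# Methods

This note documents the estimators, models and numerical conventions
implemented in `fissionet`, the assumptions behind them, and what the
synthetic-data generators do and do not emulate.

## Data model and sampling assumptions

The unit of observation is the scan sample: a partition of the observed
individuals into groups at one instant, indexed by (study day,
minute-within-session). Within a scan an individual belongs to at most
one group; singletons are real observations (they enter association
denominators and count as experienced group size 1). The default study
design — N = 12 individuals, 30 scans one minute apart per session,
four sessions on days 1, 4, 7, 10 — assumes *complete detection*
(every individual identified in every scan, as in a lab arena). All
estimators also accept incomplete detection; the half-weight
association index is provided for that case, while the simple ratio
index is the unbiased default under complete detection (the two
coincide when nobody is ever missed).

Scans one minute apart are treated as exchangeable samples of the
association state. In a population whose groups reshuffle every few
seconds this is reasonable; for slower societies the permutation and
bootstrap procedures remain valid but effective sample sizes shrink.

## Association summaries

- **CV of association indices** uses the population (divide-by-n)
  standard deviation over the off-diagonal upper triangle: the study's
  dyads are the complete set of interest, not a sample from a larger
  one. The permutation test is invariant to this convention since
  observed and null statistics share it.
- **Social differentiation S** (CV of the *true* dyadic association
  probabilities) is estimated by moments:
  `S² = max(0, var(AI) − mean[AI(1−AI)/d]) / mean(AI)²`, subtracting
  the expected binomial sampling variance from the observed variance.
  The estimator is slightly conservative in small samples (the
  plug-in noise term `AI(1−AI)` underestimates `p(1−p)` by a factor
  `1 − 1/d`) and the truncation at zero biases S upward when the true
  differentiation is far below the noise floor. A beta-binomial
  maximum-likelihood alternative (`method="mle"`) is provided; on
  well-sampled data the two agree. The power correlation
  `r = S·mean(AI)/sqrt(S²·mean(AI)² + mean[AI(1−AI)/d])` reports how
  faithfully the estimated indices track the true ones. Interpretation
  bands: S < 0.3 effectively homogeneous, > 0.5 well differentiated,
  > 2.0 extremely differentiated.

## Permutation null models

Checkerboard swaps on the group-by-individual matrix (flip a 2×2
identity/anti-identity submatrix) conserve all row sums (group sizes)
and column sums (observations per individual). Swaps are restricted to
rows of the *same sampling period*, which has two consequences: every
permuted matrix remains a valid scan partition (an individual can never
occupy two groups of one scan), and the proposal chain is symmetric, so
its stationary distribution is uniform over group assignments with the
observed per-scan group-size structure. Under a homogeneous-association
generator the observed partition is exchangeable with that null, and
the CV test's measured type-I error at α = 0.05 is 0.05 (binomial 95%
interval over 200 simulated data sets). An unrestricted (cross-period)
mode exists for experimentation but samples invalid partitions and is
anti-conservative on scan data; it is not used by the tests.

Permutations are sequential (Markov-chain) as in the classic
implementations: the chain starts at the observed matrix, and each of
the `n_permutations` (default 5000) recorded nulls follows
`flips_per_permutation` (default 1000) swap *attempts* — attempts, not
accepted swaps, are counted, so acceptance-rate differences between
data sets change effective mixing, which the autocorrelation test in
the suite monitors. P-values count ties (`null ≥ observed`) without a
+1 correction; the attainable minimum 1/n_permutations is reported
alongside. Dyadic preference/avoidance uses each dyad's own null AI
distribution with 97.5%/2.5% flags; dyads with a constant null are
untestable.

The statistic null distributions are computed from the permuted
co-membership counts over the *observed* per-dyad denominators, which
the swaps conserve.

## Network measures

Strength, eigenvector centrality (principal eigenvector, unit Euclidean
norm, non-negative; undefined for an empty network), reach, weighted
clustering, and affinity, as defined in the README. Clustering uses the
triple ratio `Σ AI_ij AI_jk AI_ki / (max AI · Σ AI_ij AI_ik)`,
normalised by the largest off-diagonal AI so a saturated neighbourhood
scores 1; a mean-triadic variant was considered and rejected because it
cannot reach 1 on weighted data. Under complete detection two exact
identities hold and are asserted at run time: mean strength =
(N−1) × mean AI, and mean gregariousness = mean strength (instantaneous
degree averaged over scans). Bootstrap SEs resample sampling periods
(not individuals) with replacement, preserving within-scan group
structure, with 1000 replicates by default.

## Lagged association rates

The estimator is the pair-persistence conditional probability

    g(τ) = Σ A_ij(t) A_ij(t+τ) / Σ A_ij(t) O_i(t+τ) O_j(t+τ)

over ordered dyads and period pairs at lag τ (A = same-group indicator,
O = identified indicator). It satisfies: frozen groups give g ≡ 1;
memoryless association gives g equal to the null rate
`mean_{i,t} deg_i(t)/(N_t − 1)`; and duplicating every scan leaves it
unchanged. Minute-scale lags never span sessions; day-scale lags pair
the same within-session minute across days (realised lags 3, 6, 9 days
under the default design). Smoothing pools numerator and denominator
over adjacent lags until a target number of contributions is reached
(ratio of sums, never mean of ratios). Precision comes from a
delete-one-block jackknife, `SE² = (k−1)/k Σ_b (g_(−b) − ḡ)²`, with
5-minute blocks within sessions (24 blocks under the default design:
6 per session × 4 sessions) or whole-day blocks (4).

## Decay models and QAIC

Five candidate forms for g(τ) are built from rapid disassociation
(g(0⁺) < 1), constant companions and casual acquaintances:
`a`, `a e^{-bτ}`, `a + c e^{-bτ}`, `a e^{-bτ} + c e^{-dτ}`, and
`f + eτ` for day-scale drift. In the two-timescale model the amplitudes
a, c are the association fractions lost on the two scales and 1/b, 1/d
are those timescales in lag units; the slow rate d and the linear slope
e may be negative (association strengthening with lag), so d is bounded
in [−5, 50] and decay rates in [0, 50] per lag unit. Amplitude sums are
kept ≤ 1 by a quadratic penalty (g(0⁺) is a probability).

Fitting maximises the binomial quasi-log-likelihood of the per-lag
estimator contributions with L-BFGS-B from 20 seeded starts (one
moment-style start plus log-uniform random rates); g is clamped to
[1e-9, 1−1e-9] inside the likelihood. The two-timescale fit is
canonicalised so b is the faster rate. Overdispersion ĉ is the Pearson
χ²/df of the most-parameterised converged candidate, floored at 1 and
shared across the candidate set so QAICs are comparable; QAIC equals
AIC when ĉ = 1. Group data violate the binomial independence assumption
(dyads of one scan are correlated through shared groups), which is
precisely what ĉ absorbs — fitted study-design data typically show
ĉ ≈ 3–8.

Between-class comparison of per-population fitted parameters uses
pooled-variance two-sample t-tests (df = n₁ + n₂ − 2) and the
Benjamini–Yekutieli step-up rule with critical values
`kα/(m Σ_{i≤m} 1/i)`, valid under arbitrary dependence among the m
comparisons; for m = 4 at α = 0.05 the largest-rank critical value is
0.024.

## Synthetic data: what it does and does not emulate

All generators emit valid, completely detected scan data under the
default study design and are bit-reproducible under a seed.

- `generate_homogeneous(p)`: iid dyadic links per scan; groups are the
  connected components. Chaining makes realised co-membership exceed p
  (at p = 0.1, N = 12 the mean AI is ≈ 0.19), but the population stays
  exchangeable — the calibration null.
- `generate_beta_dyadic(mean_p, S)`: dyad-specific probabilities drawn
  once from a Beta with given mean and CV. Because groups are the
  closure of the links, the realised co-membership CV is *not* exactly
  the Beta CV; estimator-recovery work therefore uses
  `beta_dyadic_counts`, which draws `x_ij ~ Binomial(d, p_ij)` directly
  (marginal-exact, no grouping).
- `generate_bonded_markov`: each dyad is a two-state continuous-time
  chain sampled per minute; a bonded fraction uses a slow dissociation
  hazard (default 0.01/min) and higher equilibrium, the rest a fast
  hazard (1.0/min). Day boundaries re-equilibrate (no overnight
  memory), separating the minute and day scales. Defaults put the
  expected instantaneous degree near 1, giving small, realistically
  sized shoals; the returned `dyadic_persistence(τ)` is the exact
  dyad-level mixture `Σ w_k [π_k + (1−π_k)e^{−ρ_k τ}]`, while the
  group-level estimate sits slightly above it through chaining.
- `generate_arena`: social units drift in a 120 cm circular arena,
  fish scatter around their unit centre (spread = association radius /
  (2·cohesion)), units split/merge with per-minute hazards, and groups
  are extracted by single-linkage chaining at 4 body lengths
  (body length 26.9 mm), so a 3-fish shoal can span ~8 body lengths.
  It provides transitive, spatially realistic data without closed-form
  truth — the complement of the dyadic generators.

Passing tests on these generators demonstrate internal statistical
correctness (calibration, power, recovery) under the stated sampling
models; they cannot certify behaviour under field conditions the
generators omit — observer bias, detection heterogeneity, demographic
turnover, or spatial structure beyond the arena model.

## Problem sizes in the validation suite

The test suite and the results script use deliberately sized
simulations: 200 random small data sets for the enumeration oracles;
10⁶ swap attempts for margin conservation; 200 homogeneous data sets at
500 permutations × 200 attempts for calibration; 100 replicates for
dyadic power; 5 × 10⁵ estimator contributions — the pooled scale of a
12-population study — allocated over minute lags 1–29 with the design's
triangular pair weights for model recovery (at a single-population
~1.2 × 10⁵ the fast component's (a, b) are only ~77% recoverable within
20%, an identifiability limit of integer-minute lags, not an optimiser
failure); 50 lags × 5000 trials for the parsimony check; and 200
data sets at d = 120 for differentiation recovery.

## Known limitations

- The moment estimator of S ignores denominator heterogeneity beyond
  the per-dyad noise term and truncates at zero.
- The quasi-likelihood treats per-lag contributions as a single
  binomial; jackknife SEs, not the fit's curvature, should be used for
  uncertainty on g itself.
- Day-scale curves under the default design have only three lags, so
  only the two-parameter linear model is sensibly fit there.
- The arena simulator's fission rule (uniform random splits, fixed
  offset) is phenomenological; it is intended as a data-shaped
  stress-test, not a behavioural model.
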