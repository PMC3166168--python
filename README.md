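# fissionet

Social-structure analysis for fission-fusion animal populations.

Behavioural ecologists studying fission-fusion societies — shoaling
fish, dolphins, bats, ungulates — record *scan samples*: at regular
intervals, every observed group of individually recognisable animals is
written down. `fissionet` turns such scan data into the standard
quantitative description of a society:

- **Association indices.** The simple ratio index
  `SRI = x / (x + y_AB + y_A + y_B)` estimates the proportion of time a
  dyad spends in the same group (x = periods together, y_AB = both seen
  apart, y_A/y_B = only one seen); the half-weight variant is provided
  for incomplete detection. Summaries include gregariousness (mean
  experienced group size − 1), the CV of association indices, and
  **social differentiation** S — the CV of the *true* dyadic
  association probabilities after subtracting binomial sampling noise —
  with its power correlation r.
- **Permutation null models.** Non-randomness is tested with
  margin-preserving *checkerboard swaps* of the group-by-individual
  matrix, restricted within sampling periods, so group sizes and each
  individual's number of observations are conserved. Sequential chains
  (default 5000 permutations × 1000 swap attempts) yield p-values for
  the CV of association indices, for gregariousness heterogeneity, and
  per-dyad preferred/avoided companionships (outside the 2.5–97.5% null
  quantiles).
- **Weighted network measures.** Strength `s_i = Σ_j AI_ij`,
  eigenvector centrality, reach `r_i = Σ_j AI_ij s_j`, a [0, 1]
  weighted clustering coefficient, and affinity `f_i = r_i / s_i`, with
  bootstrap standard errors over sampling periods.
- **Lagged association rates.** `g(τ)` — the probability that a dyad
  associated at time t is still associated τ units later — on minute
  and day scales, with moving-average smoothing, delete-one-block
  jackknife SEs, and a null rate for random association. Curves are fit
  by binomial quasi-likelihood to an exponential-decay model family
  (constant companions `g = a`; casual acquaintances `g = a e^{-bτ}`;
  their combination; two-timescale decay
  `g = a e^{-bτ} + c e^{-dτ}`; and a linear day-scale drift), ranked by
  QAIC `= −2 lnQL/ĉ + 2k`, and fitted parameters are compared between
  population classes with pooled t-tests under a Benjamini–Yekutieli
  correction for dependent comparisons.
- **Synthetic data.** Because scan studies are rarely deposited, a
  first-class generator suite reproduces a 12-individual lab design
  (30 scans/session, 4 sessions over 12 days) with known ground truth:
  homogeneous association, Beta-distributed dyadic preferences, a
  bonded/casual two-timescale Markov mixture, and a spatially explicit
  arena simulator with four-body-length chain-rule grouping.

## Worked example

```python
import fissionet as fn
from fissionet.synthdata import SimConfig, generate_bonded_markov, high_risk_params

obs, truth = generate_bonded_markov(SimConfig(seed=42), high_risk_params())

summ = fn.summarize(obs)
res = fn.permutation_test_cv(obs, fn.PermutationConfig(5000, 1000, seed=1))
am = fn.association_matrix(obs)
nm = fn.network_metrics(am, obs=obs, n_boot=1000, seed=2)
curve = fn.lar_curve(obs, scale="minute")
best, table = fn.select_model(fn.fit_model_set(curve.lags, curve.num, curve.den, seed=3))
```

prints (via the snippets in the docstrings):

```
mean AI = 0.336   CV of AIs = 0.66   S = 0.65 (well differentiated)
observed CV = 0.66   random CV = 0.12   P = 0.0000
    strength:  3.696 +/- 0.158
 eigenvector:  0.271 +/- 0.002
       reach: 15.391 +/- 1.263
  clustering:  0.467 +/- 0.021
    affinity:  4.146 +/- 0.168
best model: TWO_CA_RD  a=0.214  b=0.846  c=0.677  d=0.013
fast timescale 1/b = 1.2 min; slow 1/d = 75 min
```

Reading: this simulated population spends a third of its time in shared
groups (mean AI 0.34), its association CV is far above the swap-null
CV (0.66 vs 0.12, p below the attainable minimum 1/5000), and its
lagged association rate is best described by two decay timescales —
about 21% of associations dissolve on a ~1-minute scale while the
bonded fraction decays over roughly an hour — matching the generator's
fast/slow hazard mixture.

The same pipeline is scriptable from a shell:

```sh
fissionet simulate --generator bonded_markov --seed 42 -o obs.csv
fissionet associations -i obs.csv -o assoc
fissionet permtest -i obs.csv --stat cv --seed 1 -o perm.json
fissionet metrics -i obs.csv --boot 1000 --seed 2 -o net
fissionet lar -i obs.csv --scale minute -o lar.csv
fissionet fit -i obs.csv --seed 3 -o fit.json
fissionet compare --by-class params.csv -o comparison.csv
```

## Layout

```
src/fissionet/
  obsdata.py     scan-sample data model, CSV I/O, GBI matrix, dyad counts
  association.py association indices and population summaries
  nullmodels.py  checkerboard-swap permutation tests (numba kernel)
  netmetrics.py  weighted network measures + period bootstrap
  lar.py         lagged association rates, smoothing, jackknife
  larmodels.py   decay-model family, quasi-likelihood fits, QAIC, t-tests
  synthdata.py   ground-truth generators (homogeneous, beta, Markov, arena)
  cli.py         `fissionet` command-line pipeline
docs/methods.md  models, estimators, numerical choices, limitations
```
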