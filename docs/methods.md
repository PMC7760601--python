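# Methods

## Simulation model

A simulated experiment consists of unit-level measurements of one quality
attribute for two products, reference (R) and test (T), each manufactured in
`n_batches` batches with `n_units` measured units per batch. Measurements are
strictly positive and multiplicative, as is standard for rheological and
related attributes, so all noise acts on the log scale:

- population values: TVP_R = 1 (the attribute is analysed as a ratio, so the
  reference scale is arbitrary), TVP_T = `tr_ratio`/100;
- batch means: P_jk = TVP_j · exp(η_IBV) with η_IBV ~ N(0, ω²_IBV),
  drawn independently per batch and per product;
- unit values: P_ijk = P_jk · exp(η_ABV) with η_ABV ~ N(0, ω²_ABV),
  independent per unit.

Variabilities are supplied as percent coefficients of variation and injected
as log-scale standard deviations via **ω = CV/100**. This is a deliberate
choice of the model definition, not the exact lognormal moment relation
σ = √(ln(1+(CV/100)²)); for CV ≤ 20 % the two differ by under 2 %, and only
the widening rule (below) uses the exact relation, because its published
constants are defined through it. Keeping both, each in its own context, is
intentional; they must not be conflated.

A single batch (`n_batches = 1`) still draws its own batch-level factor:
the model makes no exception for single batches, which is why inter-batch
variability degrades single-batch designs even though it cannot be estimated
from them.

## Equivalence test

The statistic is the geometric mean ratio over all pooled units,
θ = exp(mean log T − mean log R). A non-parametric bootstrap resamples each
product independently with replacement; the percentile 90 % CI is the
interval between the 5th and 95th percentiles of the resampled θ values
(α = 0.05 each side), computed by linear interpolation of order statistics
(the "type 7" convention, numpy's default; at B = 10⁴ the estimator choice
moves the bounds by ~10⁻⁴). Similarity is declared iff the whole CI lies in
[0.9, 1/0.9], both comparisons inclusive. The upper limit is carried at full
precision (1.111…), displayed as 111.11 %.

### Resampling strategies

- **stratified** (default): batches fixed, `n_units` units redrawn with
  replacement within each batch. The CI width then reflects within-batch
  (measurement) variability, while batch effects displace the observed GMR.
  This scheme reproduces published power surfaces for multi-batch designs
  (spot-checked cells at 3–12 batches agree within Monte-Carlo error) and is
  the package default.
- **flat**: all `n_batches·n_units` units pooled and redrawn. The CI inflates
  with total variability; its width grows stochastically with both IBV and
  ABV (a property the test suite checks on averages over 200 experiments).
- **hierarchical**: batches redrawn with replacement, then units within each
  drawn batch. Statistically the most honest for clustered data but very
  conservative at few batches: with 2 batches the 90 % percentile interval
  includes the same-batch-twice draws (probability ¼ each) and spans
  essentially the full batch range, collapsing power. Notably, published
  power values for 1–2-batch designs — including the reported anomaly that
  two batches perform *worse* than one — are reproduced by this scheme and
  not by the others, while 3+-batch values are reproduced only by the
  stratified scheme. No single scheme matches both regimes; the package
  applies one scheme uniformly and defaults to stratified, which covers
  every design for which the fixed-range test is practically recommended.
  At `n_batches = 1` all three schemes coincide.

## Power estimation

The probability of similarity for a scenario is the fraction of simulated
experiments whose CI passes, with the binomial 95 % half-width
1.96·√(p(1−p)/n) reported alongside. Reference depth is 1000 experiments ×
10,000 bootstraps per scenario (the `RunConfig` default, used by the CLI);
library and test defaults are 300 × 1000, which reproduces probabilities
within ~±4.5 pp at p ≈ 0.8. The acceptance script uses 2500 × 2000 for the
pinned scenarios (Monte-Carlo half-width ≈ ±1.6 pp) and 300 × 200 for the
zero-variance scenario, whose outcome is exact at any depth. These sizes are
the package's own choice of desk-scale precision; the full 2205-scenario
sweep at reference depth is a batch job for the resumable `grid` command, not
part of the test suite.

### Randomness and reproducibility

All randomness derives from one master seed through
`numpy.random.SeedSequence(seed, spawn_key=(*scenario_key, experiment_index,
stream))` with stream 0 for data generation and stream 1 for the bootstrap.
Consequences, all tested: any experiment can be regenerated in isolation;
simulation and inference noise are decoupled; the worker count of a parallel
sweep cannot change any number; and draw order within an experiment
(reference before test, batch means before unit noise, row-major units, a
fixed variate count even at zero variance) is frozen for bit-reproducibility.

## Sample-size recommendation

Given grid results for a (T/R, IBV, ABV) condition, the recommended design is
the one meeting the power target (default 0.80, the customary threshold)
with the fewest total observations N_B·N_U, ties broken toward fewer
batches. Because equal-total designs with more batches handle inter-batch
variability better, a `prefer="batches"` ordering (fewest batches first) is
exposed as an alternative; neither ordering extrapolates beyond the designs
actually present in the grid, and an infeasible condition returns the
best-powered design flagged as such.

## Reference-scaled widening

For attributes whose variability defeats any feasible design, acceptance
limits may be widened in proportion to the **total** log-scale SD of the
reference product, s_R: limits = exp(±κ·s_R), the mechanism used for Cmax of
highly variable drugs but anchored to a 10 % range. The constant
κ = ln(1/0.9)/s₀ with s₀ = √(ln(1+(CV₀/100)²)) makes the limits equal exactly
(0.9, 1/0.9) at the anchor variability CV₀; κ(10 %) = 1.056, κ(20 %) = 0.532,
κ(30 %) = 0.3589. The base log-limit must be ln(1/0.9), not ln(1.1) — only
the former yields these constants. Widened limits are computed and reported
but never applied by default (the `--scaled-cv0` flag of `batchequiv test`
opts in), since the rule is a proposal rather than an accepted criterion, and
no anchor CV₀ is canonical; s_R estimated from data is the plain sample SD of
log reference values, i.e. total variability without decomposition.

## What the generator does and does not emulate

The generator reproduces the hierarchical lognormal structure, the grid of
conditions and the sampling depths under which the power surfaces were
originally mapped. It does not emulate features of real laboratory data such
as non-lognormal tails, correlated batch effects between products (e.g.
shared raw-material lots), instrument drift within a measurement session, or
missing units. Passing tests therefore demonstrate correctness of the
machinery and calibration under the stated model, not robustness of the
equivalence test to violations of it.

## Numerical choices and degenerate inputs

- Quantiles: linear interpolation of order statistics throughout (type 7).
- Zero variance collapses every resample to a point: the CI is degenerate at
  the observed GMR and the verdict is deterministic (power exactly 1 inside
  the limits, 0 outside) — preserved exactly because `Normal(0, 0)` draws
  consume their stream slots and return 0.
- Acceptance limits are compared inclusively; the exact values 0.9 and 1/0.9
  are used, not their 4-decimal renderings.
- Wide tables round probabilities half-to-even to integer percent for
  display; the long CSV always retains full precision.
- Table cells are validated against a full factorial layout; a ragged grid is
  an error naming the missing cells rather than a silently incomplete table.

## Known limitations

- Published power tables cannot be matched bitwise — the original RNG and
  seeds are unknown — only within Monte-Carlo error; and, as noted above,
  their 1–2-batch and 3+-batch regions appear to reflect different
  resampling schemes, so a uniform scheme cannot reproduce both.
- The bootstrap is percentile-only; no BCa or parametric (TOST) intervals.
- No multiplicity adjustment across attributes: when many parameters are
  compared, the chance that at least one fails by accident grows, which
  argues for sizing on the most variable parameter rather than adjusting α.
- Recommendations are restricted to designs present in the evaluated grid;
  no closed-form power approximation or continuous optimisation is offered.
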