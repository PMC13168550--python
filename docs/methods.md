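# Methods

## Detection process model

Each occupied site is an independent square landscape (edge 1500 m,
225 ha) with the survey point at its center. The generative model for one
visit is:

1. **Territory placement.** The number of birds is `Poisson(density × area)`.
   Territory centers ("nests") are placed by sequential spatial inhibition:
   candidates are drawn uniformly and rejected while closer than the
   inhibition radius `0.5 · sqrt(1/density)` (half the mean grid spacing) to
   any accepted nest, up to 1,000 attempts per bird, after which remaining
   birds are placed unconstrained with a warning. This produces the
   semi-regular spacing typical of territorial songbirds. An `exactly_one`
   mode instead places a single nest uniformly at random.
2. **Movement.** Within a visit of duration t = 10 min a bird relocates as a
   Poisson process at 1 move/min. Its initial position and every relocation
   are independent draws from a bivariate normal centered on the nest with
   per-axis SD σ_m (0, 10, 25, 50 or 100 m; σ_m = 0 is a stationary bird);
   position is piecewise-constant between moves. Positions are redrawn
   afresh each visit — visits are exchangeable by construction.
3. **Cues and perceptibility.** Each bird produces cues as an independent
   Poisson process at ν = 0.25 cues/min. A cue emitted at distance d from
   the survey point is detected with half-normal probability
   `g(d) = exp(−(d/τ)²)`, τ = 60 m by default (90 and 120 m variants are
   config options). The visit records a detection iff any cue from any bird
   is detected. For stationary birds this gives the closed form
   `P(detect) = 1 − exp(−ν t Σ_k g(d_k))`, which the test suite verifies by
   Monte Carlo.
4. **Occupancy definition.** A site is *occupied* when at least one bird's
   core territory — the disc of radius 2σ_m around the nest, holding ~86%
   of relocations — overlaps the sampling range, the disc where a single
   cue is detected with more than 6% probability
   (`r = τ·sqrt(ln(1/0.06))` ≈ 100 m for τ = 60). Occupied layouts are
   rejection-sampled until this holds, so every occupied site has at least
   one plausibly detectable bird; unoccupied sites are all-zero rows.

A scenario simulates `round(ψ·M)` occupied sites (default M = 200,
N = 20 visits). Reproducibility is hierarchical: the scenario seed spawns
per-site `SeedSequence` children, which spawn per-visit children, so the
same config and seed give a bit-identical history, serially or in parallel.

Two implementation notes. All birds of a visit are simulated in one
vectorized pass over flattened cue/move event arrays; this is equivalent in
distribution to a per-bird event loop. Birds whose nests are so distant
that their expected number of detected cues over the whole site is below
1e−7 (beyond `τ·sqrt(ln(ν t N /1e−7)) + 7σ_m`) are dropped before the visit
loop.

The module also provides parametric generators (zero-inflated binomial,
zero-inflated beta-binomial with `p_i ~ Beta(α, β)`, and Royle–Nichols)
used for calibration, parameter-recovery checks and the two-landscape
worked example.

### What the generator does and does not emulate

It emulates the detection side of manually vetted PAM or auditory point
counts: many repeat visits, availability limited by cue production, and
perceptibility declining with distance. It does **not** model observer
error or false positives, date/weather covariates on detection, closure
violations (territory shifts, mortality), classifier scoring of audio, or
edge effects at the landscape boundary. Passing tests therefore show that
the estimators and diagnostics behave as described under spatial
heterogeneity alone; real field data add further heterogeneity sources the
simulator deliberately omits.

## Occupancy models

All three likelihoods depend on the data only through the per-site
detection counts `D_i` (sufficiency under within-site constant per-visit
probability), so fitting operates on the frequency vector of D over
{0..N}; the fitters also accept a raw (possibly non-integer) frequency
vector, which is how the expected-frequency worked example is fit.

- **basic**: `log L = Σ_i log[ψ·Binom(D_i; N, p) + (1−ψ)·1{D_i=0}]`,
  optimized on (logit ψ, logit p).
- **ZIBB**: beta-binomial cell probabilities via log-gamma
  (`betaln(d+α, N−d+β) − betaln(α, β)`), optimized on
  (logit ψ, log α, log β).
- **RN**: site likelihood `Σ_{B=0}^{K} Poisson(B; λ)·Binom(D_i; N,
  1−(1−r)^B)`, optimized on (log λ, logit r); derived occupancy
  `ψ̂ = 1 − e^{−λ̂}` (exact identity, tested to machine precision).
  K defaults to 60 and doubles automatically while the Poisson tail above K
  at λ̂ exceeds 1e−8.

Numerical choices: L-BFGS-B with ftol 1e−10, one moment-based start plus 5
seeded random restarts (SD 2 on the transformed scale); ZIBB gets an extra
high-concentration start (α+β = 1e7 at the pooled detection rate) so
homogeneous data can never fit worse under ZIBB than under the nested
binomial — the limit is approached at rate O(MN²/(α+β)), so the nested
log-likelihood bound holds to about 1e−3 at double precision, not exactly.
Standard errors come from the inverse of a central finite-difference
Hessian at the optimum (relative step 1e−4); a non-positive-definite
Hessian marks SEs, and hence Wald intervals, unavailable. Wald CIs for
occupancy are computed on logit ψ (basic, ZIBB) or log λ (RN) and
back-transformed, keeping endpoints in [0, 1]. Estimates with ψ̂ > 0.99 are
flagged as boundary fits. Histories that are all-zero or all-one are
rejected with explicit errors (occupancy and detection are not separately
identifiable there) rather than silently returned as boundary fits.

With N = 2 the three-parameter ZIBB is fit to three cells: the MLE is a
one-dimensional ridge of saturated fits on which ψ̂ is not identified (any
ψ above the value matching the zero cell can be compensated by a more
bimodal beta). The fit is attempted with a warning; the reported ψ̂ is
wherever the optimizer lands on the ridge and should not be interpreted.
This matters when comparing mean ZIBB errors at T = 2 across
implementations: the magnitude of that "bias" is an optimizer-path
artifact, not a property of the model.

## Exact tests

Both diagnostics compare an observed detections-per-site distribution with
a fitted null: the heterogeneity test against a binomial fit to all
occupied sites (simulated mode, truth known) or a zero-truncated binomial
fit to the detected sites (field mode); the goodness-of-fit test against a
fitted occupancy model's expected distribution over all M sites. Expected
counts are rounded to integers by largest-remainder repair (total
preserved exactly, each cell moved by < 1, ties broken by category index).

Because many cells have small expected counts, chi-squared asymptotics are
invalid and Monte Carlo exact tests are used. Two constructions are
implemented, differing in whether the null distribution is treated as
fixed or as a second sample:

- **one-sample multinomial** (`method='multinomial'`): tables are sampled
  from the fitted null pmf at the observed total; p is the fraction of
  tables whose multinomial probability is at most the observed table's
  (probability ordering, add-one correction). Sampling uses the pmf itself
  rather than the rounded counts — rounding small cells to zero would put
  observed mass on zero-probability categories and destroy calibration.
- **two-sample Fisher** (`method='fisher'`): Fisher's exact test on the
  2 × K table stacking observed over integer-expected counts, Monte Carlo
  over the margins-fixed hypergeometric null (the `simulate.p.value`
  construction of R's `fisher.test`). Treating the expected distribution
  as a second sample of M sites roughly doubles the sampling variance,
  making this test noticeably more conservative.

Defaults: the heterogeneity test uses the one-sample construction and the
model GOF test uses the two-sample Fisher construction. These defaults
were calibrated against the reference analyses this package reimplements:
on matched simulation grids the heterogeneity-flag rate reproduces the
reference value only under the one-sample test, while the three models'
GOF failure rates reproduce the reference values only under the
observed-vs-expected Fisher table. Both methods are exposed on both tests.
The Monte Carlo sample is 10,000 tables by default, doubling automatically
while p is within two Monte Carlo standard errors of α = 0.05 (capped at
160,000); p-values are reported with their MC standard error and flagged
at p < 0.05 with no multiple-testing correction across the grid.

Under the null (parameters estimated from the data) both constructions are
calibrated-to-conservative: measured null rejection rates are ≈0.04
(heterogeneity, one-sample) and ≈0.01–0.03 (GOF) at α = 0.05.

## Experiment grid

The study grid crosses six density levels (0.1, 0.25, 0.5, 1, 2 birds/ha,
plus exactly-one), five movement SDs (0–100 m) and three occupancy levels
(0.2, 0.5, 0.8). Each (density, σ_m, replicate) unit simulates the
ψ = 0.8 history once (160 occupied sites) and reaches the lower occupancy
levels by uniform random subsetting of occupied rows (padding with
unoccupied all-zero rows to keep M = 200), mirroring how such grids are
generated economically. Shortened histories take the first T columns
(simulated mode) or a per-site independent shuffle followed by the first T
(field mode, which removes date structure). Per dataset and T, all three
models are fit and tested; recorded metrics are the occupancy error
`100·(ψ̂ − mean(z))` in percentage points, Wald-CI coverage and width
(where SEs exist), boundary and convergence flags, and both tests'
p-values. Work units run in parallel under joblib with per-unit seed
streams, merge deterministically, and can be cached to JSON for resumable
runs. Summaries (mean/SD error, coverage, CI width, boundary rate, GOF
failure rate, heterogeneity-flag rate) are recomputed from the per-dataset
records; error summaries are available both including and excluding
boundary fits.

### Problem sizes

Default replication in `analysis/03_run_scenario_grid.py` is 10 replicates
per scenario (900 simulated histories, ~2,700 datasets after occupancy
subsetting), a scale chosen so the grid runs in a few hours on one core
and parallelizes linearly; the acceptance test suite runs the same grid at
2 replicates with T ∈ {2, 20}, and the two-landscape example uses 200–300
replicates of the cheap parametric generator. The simulator itself costs
roughly 0.3–3 s per 200-site scenario depending on density.

## Known limitations

- The reported RN mean error at many visits is sensitive to the exact
  degree of overdispersion the simulator produces; small differences in
  movement/placement conventions between agent-based simulators shift it
  by several percentage points even when heterogeneity-diagnosis rates and
  basic-model biases agree.
- Mean ZIBB error at T = 2 is not a reproducible quantity (ridge
  non-identifiability, above).
- No covariates on ψ or p, no Bayesian fitting, no multi-scale or dynamic
  models, no distance-sampling channel; missing visits are storable in the
  CSV format but rejected at fit time, since all three likelihoods assume
  complete N-visit histories.
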