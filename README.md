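# occuhet

Detection heterogeneity in single-season avian occupancy models: an
agent-based simulator of point-count / passive-acoustic detection histories,
three covariate-free occupancy estimators, and exact tests for diagnosing
heterogeneity and poor model fit.

## The problem

Occupancy models estimate the proportion of sites occupied by a species,
ψ, from repeat-visit detection–nondetection data, correcting for imperfect
per-visit detection probability p. The standard single-season model assumes
p is constant across occupied sites. But two ubiquitous spatial processes
violate that assumption even in perfectly homogeneous habitat: the random
position of each bird's territory relative to the survey point, and
within-territory movement that changes a bird's distance — and hence its
audibility — from visit to visit. Sites whose resident birds happen to sit
near the survey point have p near 1; sites overlapping only the margin of a
territory have p near 0. Passive acoustic monitoring (PAM), which collects
10–21 "visits" per site cheaply, makes this site-level heterogeneity both
more visible and more consequential.

`occuhet` simulates this detection process mechanistically and quantifies
its effect on three estimators:

- **basic** — zero-inflated binomial: `D_i ~ ZIBinom(N, p, 1-ψ)`, constant p;
- **ZIBB** — zero-inflated beta-binomial: site-level `p_i ~ Beta(α, β)`,
  integrated out analytically;
- **RN** — Royle–Nichols: latent site abundance `B_i ~ Poisson(λ)` with
  per-individual detection r, `p_i = 1 − (1−r)^{B_i}`, and derived occupancy
  `ψ = 1 − e^{−λ}`;

plus exact Monte Carlo tests of whether the observed detections-per-site
distribution deviates from a fitted binomial / zero-truncated binomial null
(heterogeneity test) or from each fitted model's expected distribution
(goodness-of-fit test).

## The simulator

Each occupied site is a 1.5 × 1.5 km landscape with a surveyor at the
center. Territory centers are placed by sequential spatial inhibition at a
chosen density (or exactly one bird); during each 10-min visit a bird
relocates at 1 move/min (bivariate-normal around its territory center,
per-axis SD σ_m ∈ {0, 10, 25, 50, 100} m) and produces cues at 0.25/min.
A cue at distance d is detected with half-normal probability
`g(d) = exp(−(d/τ)²)` with effective detection radius τ = 60 m (~97% at
10 m, ~50% at 50 m, ~6% at 100 m). A site counts as occupied when at least
one bird's core territory (radius 2σ_m) overlaps the 100-m sampling range;
layouts are rejection-sampled until that holds. See `docs/methods.md` for
the full model and every default.

## Worked example

```python
import numpy as np
from occuhet import (ScenarioConfig, simulate_scenario, fit_basic, fit_zibb,
                     heterogeneity_test, gof_test)

cfg = ScenarioConfig(density=0.25, movement_sd=10.0, psi=0.8,
                     n_sites=200, n_visits=20, seed=42)
history = simulate_scenario(cfg)          # 200 x 20 binary matrix + truth
rng = np.random.default_rng(0)

het = heterogeneity_test(history, mode="simulated", rng=rng)
basic = fit_basic(history)
zibb = fit_zibb(history)
print(f"heterogeneity p = {het.p_value:.4f} (flagged: {het.flagged})")
print(f"basic: psi_hat = {basic.psi_hat:.2f}, "
      f"GOF p = {gof_test(basic, history, rng).p_value:.4f}")
print(f"zibb:  psi_hat = {zibb.psi_hat:.2f}, "
      f"GOF p = {gof_test(zibb, history, rng).p_value:.4f}")
```

prints

```
heterogeneity p = 0.0001 (flagged: True)
basic: psi_hat = 0.78, GOF p = 0.0001
zibb:  psi_hat = 0.80, GOF p = 0.9440
```

True occupancy is 0.80. The detection counts are strongly overdispersed
(heterogeneity flagged), the constant-p model is rejected by the
goodness-of-fit test even though its 20-visit estimate is only mildly
biased, and the beta-binomial model both fits the distribution and
recovers the true occupancy. At fewer visits the basic model's
underestimate grows sharply — that trade-off is what the scenario grid
quantifies.

The same machinery is exposed on the command line
(`occuhet simulate|fit|test|grid|summarize`).

## The analysis

Numbered drivers under `analysis/` rebuild the study end to end; each
writes its tables under `results/`:

1. `01_detection_geometry.py` — closed-form perceptibility, sampling range
   and core-territory areas.
2. `02_two_landscapes.py` — two landscapes (ψ=0.5 with constant p=0.8 vs
   ψ=0.8 with `p_i ~ Beta(0.4, 0.4)`) that are indistinguishable at 2 visits:
   the basic model estimates 50.0% and ~51% occupancy respectively, and
   still only ~63% for the second landscape at 10 visits.
3. `03_run_scenario_grid.py` — the 90-scenario grid (6 densities × 5
   movement SDs × 3 occupancy levels, 200 sites × 20 visits), fitting all
   three models to full and shortened histories and running both exact
   tests; `--replicates`, `--jobs` and `--resume` control scale.
4. `04_grid_headline_rates.py` — headline diagnosis rates and mean
   occupancy errors from the grid records.

On the grid (at 2 replicates per scenario), detection heterogeneity is
flagged in 93% of full-occupancy datasets; the basic model fails
goodness-of-fit on well over half of 20-visit histories (62% in this run)
and underestimates occupancy most severely at 2 visits (−7.6 points), the
RN model fails 41% and drifts from under- to overestimation as visits
accumulate, and the ZIBB model never fails and is nearly unbiased.

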