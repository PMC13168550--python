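"""Two landscapes that short detection histories cannot tell apart.

Landscape A: 50% of sites occupied, constant detection probability p = 0.8.
Landscape B: 80% occupied, site detection probability p_i ~ Beta(0.4, 0.4)
(most sites near 0 or near 1 -- the signature of territory position and
movement relative to the survey point).

With two visits per site the expected detections-per-site distributions of
the two landscapes are nearly identical, and the basic zero-inflated
binomial model fit to landscape B badly underestimates occupancy (~52% when
truth is 80%); with ten visits the distributions separate but the basic
model still underestimates (~64%).  This driver fits the basic model to the
exact expected frequencies and to >= 200 simulated replicates of each
landscape and writes results/two_landscapes.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from occuhet import fit_basic, simulate_betabinomial_history
from occuhet.models import _betabinom_logpmf

OUT = Path(__file__).resolve().parents[1] / "results"


def expected_zib_counts(psi: float, p: float, n_visits: int, m: int) -> np.ndarray:
    pmf = stats.binom.pmf(np.arange(n_visits + 1), n_visits, p)
    cell = psi * pmf
    cell[0] += 1 - psi
    return m * cell


def expected_zibb_counts(psi: float, a: float, b: float, n_visits: int,
                         m: int) -> np.ndarray:
    pmf = np.exp(_betabinom_logpmf(n_visits, a, b))
    cell = psi * pmf
    cell[0] += 1 - psi
    return m * cell


def mean_estimate(psi, a, b, n_visits, n_rep, rng):
    est = []
    for _ in range(n_rep):
        h = simulate_betabinomial_history(psi, a, b, 200, n_visits, rng)
        est.append(fit_basic(h).psi_hat)
    return 100 * float(np.mean(est)), 100 * float(np.std(est) / np.sqrt(len(est)))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--replicates", type=int, default=200)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(args.seed)
    rows = []

    fa = fit_basic(expected_zib_counts(0.5, 0.8, 2, 200))
    print(f"landscape A (psi=0.5, p=0.8), N=2, expected-frequency fit: "
          f"{100 * fa.psi_hat:.1f}% occupied")
    rows.append({"landscape": "A", "n_visits": 2, "kind": "expected",
                 "basic_psi_pct": 100 * fa.psi_hat, "se_pct": 0.0})

    for n_visits in (2, 10):
        fb = fit_basic(expected_zibb_counts(0.8, 0.4, 0.4, n_visits, 200))
        rows.append({"landscape": "B", "n_visits": n_visits, "kind": "expected",
                     "basic_psi_pct": 100 * fb.psi_hat, "se_pct": 0.0})
        mean, se = mean_estimate(0.8, 0.4, 0.4, n_visits, args.replicates, rng)
        rows.append({"landscape": "B", "n_visits": n_visits, "kind": "simulated",
                     "basic_psi_pct": mean, "se_pct": se})
        print(f"landscape B (psi=0.8, Beta(0.4,0.4)), N={n_visits}: "
              f"expected-frequency fit {100 * fb.psi_hat:.1f}%, "
              f"mean over {args.replicates} simulations {mean:.1f}% "
              f"(+/- {se:.2f})")

    pd.DataFrame(rows).to_csv(OUT / "two_landscapes.csv", index=False)
    print(f"wrote {OUT / 'two_landscapes.csv'}")


if __name__ == "__main__":
    main()
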