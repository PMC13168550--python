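"""Exact tests for detection heterogeneity and occupancy-model fit.

Two diagnostics, both comparing an observed distribution of detections per
site against the distribution expected under a fitted null:

* **Detection heterogeneity test** -- if detection probability is constant
  across occupied sites, the per-site counts ``D_i`` are binomial.  In
  *simulated* mode (truth known) a binomial null is fit to all occupied
  sites, including those with zero detections; in *field* mode (truth
  unknown) a zero-truncated binomial null is fit to the sites with at least
  one detection.
* **Goodness-of-fit test** -- the observed counts over all M sites are
  compared against the distribution expected by a fitted occupancy model.

Because many count categories have small expected frequencies, classical
chi-squared p-values are invalid and exact tests are used.  Two Monte Carlo
exact constructions are provided:

* ``method='multinomial'`` -- one-sample exact multinomial GOF test: tables
  are sampled from the null pmf at the observed total and the p-value is the
  proportion with probability no greater than the observed table's
  (probability ordering, add-one correction).  The null distribution is
  treated as fixed, which gives the test full one-sample power.
* ``method='fisher'`` -- Fisher's exact test on the 2 x K contingency table
  whose rows are the observed counts and the integer-rounded expected
  counts: tables are sampled from the margins-fixed hypergeometric null
  (as R's ``fisher.test`` with ``simulate.p.value``).  Treating the expected
  distribution as a second sample of M sites roughly doubles the sampling
  variance, making this construction noticeably more conservative.

The heterogeneity test defaults to the one-sample multinomial construction;
the model goodness-of-fit test defaults to the two-sample Fisher
construction.  A dataset is flagged as heterogeneous, or a model as failing,
when p < 0.05.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, special, stats

from .simulate import DetectionHistory
from .models import ModelFit, expected_distribution

__all__ = [
    "TestResult",
    "fit_binomial_null",
    "fit_ztb_null",
    "largest_remainder_round",
    "exact_gof_pvalue",
    "fisher_exact_2xk",
    "heterogeneity_test",
    "gof_test",
    "ALPHA",
]

ALPHA = 0.05
DEFAULT_N_MC = 10_000
#: cap on automatic doubling of the Monte Carlo sample near the alpha boundary
MAX_N_MC = 160_000


@dataclass
class TestResult:
    """Outcome of one exact test."""

    name: str
    observed: np.ndarray
    expected: np.ndarray
    p_value: float
    mc_error: float
    n_mc: int
    flagged: bool
    #: detection-count value of the first category (0, or 1 for zero-truncated)
    d_offset: int = 0
    null_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["observed"] = np.asarray(self.observed).tolist()
        d["expected"] = np.asarray(self.expected).tolist()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def fit_binomial_null(D: np.ndarray, n_visits: int) -> float:
    """Binomial MLE of the per-visit detection probability.

    ``D`` holds detection counts for all occupied sites, including zeros.
    """
    D = np.asarray(D, dtype=float)
    if len(D) < 2:
        raise ValueError("need at least 2 sites to fit the binomial null")
    return float(D.sum() / (len(D) * n_visits))


def fit_ztb_null(D: np.ndarray, n_visits: int) -> float:
    """Zero-truncated-binomial MLE of the per-visit detection probability.

    ``D`` holds counts for sites with at least one detection.  The MLE solves
    ``mean(D) = N p / (1 - (1-p)^N)`` for p in (0, 1].
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 1):
        raise ValueError("zero-truncated null requires all D_i >= 1")
    mean_d = float(D.mean())
    n = n_visits
    if mean_d >= n:
        return 1.0

    def gap(p):
        return n * p / -np.expm1(n * np.log1p(-p)) - mean_d

    # gap(p) -> 1 - mean_d <= 0 as p -> 0 and gap(1) = n - mean_d >= 0
    if mean_d <= 1.0:
        return 1e-12
    return float(optimize.brentq(gap, 1e-12, 1.0 - 1e-12, xtol=1e-12))


def ztb_pmf(p: float, n_visits: int) -> np.ndarray:
    """Zero-truncated binomial pmf over D in {1..N}."""
    d = np.arange(1, n_visits + 1)
    pmf = stats.binom.pmf(d, n_visits, p)
    denom = -np.expm1(n_visits * np.log1p(-p)) if p < 1 else 1.0
    return pmf / denom


def largest_remainder_round(expected: np.ndarray, total: int = None) -> np.ndarray:
    """Round expected counts to integers preserving the total exactly.

    Largest-remainder method: floor everything, then hand out the remaining
    units to the categories with the largest fractional parts (ties broken by
    category index).  Each category moves by less than 1.
    """
    expected = np.asarray(expected, dtype=float)
    if total is None:
        total = int(round(expected.sum()))
    base = np.floor(expected).astype(int)
    short = total - int(base.sum())
    if short < 0:
        raise ValueError("expected counts exceed the requested total")
    frac = expected - np.floor(expected)
    order = np.lexsort((np.arange(len(expected)), -frac))
    base[order[:short]] += 1
    return base


def _multinomial_logpmf(tables: np.ndarray, log_probs: np.ndarray,
                        log_coef_n: float) -> np.ndarray:
    """Multinomial log-probability of each row of ``tables`` (0*log0 = 0)."""
    with np.errstate(invalid="ignore"):
        contrib = np.where(tables > 0, tables * log_probs, 0.0)
    return log_coef_n - special.gammaln(tables + 1).sum(axis=1) + contrib.sum(axis=1)


def exact_gof_pvalue(
    observed: np.ndarray,
    expected: np.ndarray,
    rng: np.random.Generator,
    n_mc: int = DEFAULT_N_MC,
    alpha: float = ALPHA,
) -> tuple[float, float, int]:
    """Monte Carlo exact multinomial goodness-of-fit p-value.

    Samples multinomial tables from the expected proportions at the observed
    total and reports the proportion whose probability under the null is at
    most that of the observed table (with an add-one correction).  The Monte
    Carlo sample doubles automatically while the p-value is within two Monte
    Carlo SEs of ``alpha``, up to a cap.

    Returns ``(p_value, mc_error, n_mc_used)``.
    """
    observed = np.asarray(observed, dtype=int)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape or observed.ndim != 1:
        raise ValueError("observed and expected must be 1-D and congruent")
    if len(observed) < 2:
        raise ValueError("need at least 2 categories")
    total = int(observed.sum())
    if not np.isclose(expected.sum(), total):
        raise ValueError("observed and expected totals differ")
    probs = expected / expected.sum()
    with np.errstate(divide="ignore"):
        log_probs = np.log(probs)
    log_coef = float(special.gammaln(total + 1))
    # a zero-probability category with observed mass gives the observed table
    # probability zero: the strongest possible evidence against the null
    logp_obs = float(
        _multinomial_logpmf(observed[None, :], log_probs, log_coef)[0]
    )
    tol = 1e-9 * max(1.0, abs(logp_obs)) if np.isfinite(logp_obs) else 0.0

    hits = 0
    used = 0
    while True:
        draw = min(n_mc, MAX_N_MC) - used if used else n_mc
        tables = rng.multinomial(total, probs, size=draw)
        logp = _multinomial_logpmf(tables, log_probs, log_coef)
        if np.isfinite(logp_obs):
            hits += int(np.sum(logp <= logp_obs + tol))
        used += draw
        p = (1.0 + hits) / (used + 1.0)
        mc_error = float(np.sqrt(p * (1.0 - p) / used))
        if abs(p - alpha) >= 2.0 * mc_error or used >= MAX_N_MC:
            return p, mc_error, used
        n_mc = used * 2


def fisher_exact_2xk(
    observed: np.ndarray,
    expected_int: np.ndarray,
    rng: np.random.Generator,
    n_mc: int = DEFAULT_N_MC,
    alpha: float = ALPHA,
) -> tuple[float, float, int]:
    """Monte Carlo Fisher's exact test on a 2 x K observed-vs-expected table.

    The table stacks the observed counts over a second row of integer
    expected counts; columns where both rows are zero are dropped.  Tables
    are sampled from the margins-fixed (multivariate hypergeometric) null and
    ranked by their Fisher probability, with an add-one correction.  The
    Monte Carlo sample doubles automatically near the ``alpha`` boundary.

    Returns ``(p_value, mc_error, n_mc_used)``.
    """
    observed = np.asarray(observed, dtype=int)
    expected_int = np.asarray(expected_int, dtype=int)
    if observed.shape != expected_int.shape or observed.ndim != 1:
        raise ValueError("observed and expected must be 1-D and congruent")
    tab = np.vstack([observed, expected_int])
    cols = tab.sum(axis=0)
    tab = tab[:, cols > 0]
    cols = cols[cols > 0]
    if tab.shape[1] < 2:
        raise ValueError("need at least 2 non-empty categories")
    rows = tab.sum(axis=1)
    const = (special.gammaln(rows + 1).sum() + special.gammaln(cols + 1).sum()
             - special.gammaln(rows.sum() + 1))
    logp_obs = float(const - special.gammaln(tab + 1).sum())
    tol = 1e-9 * max(1.0, abs(logp_obs))
    sampler = stats.random_table(rows, cols)

    hits = 0
    used = 0
    while True:
        draw = min(n_mc, MAX_N_MC) - used if used else n_mc
        tables = sampler.rvs(size=draw, random_state=rng)
        logp = const - special.gammaln(tables + 1).sum(axis=(1, 2))
        hits += int(np.sum(logp <= logp_obs + tol))
        used += draw
        p = (1.0 + hits) / (used + 1.0)
        mc_error = float(np.sqrt(p * (1.0 - p) / used))
        if abs(p - alpha) >= 2.0 * mc_error or used >= MAX_N_MC:
            return p, mc_error, used
        n_mc = used * 2


def _run_exact(observed, expected_float, expected_int, rng, method, n_mc, alpha):
    if method == "multinomial":
        return exact_gof_pvalue(observed, expected_float, rng, n_mc=n_mc,
                                alpha=alpha)
    if method == "fisher":
        return fisher_exact_2xk(observed, expected_int, rng, n_mc=n_mc,
                                alpha=alpha)
    raise ValueError(f"method must be 'multinomial' or 'fisher', got {method!r}")


def heterogeneity_test(
    history: DetectionHistory,
    mode: str,
    rng: np.random.Generator,
    alpha: float = ALPHA,
    n_mc: int = DEFAULT_N_MC,
    method: str = "multinomial",
) -> TestResult:
    """Exact test for site-level detection heterogeneity.

    ``mode='simulated'`` fits a binomial null to all occupied sites (truth
    flags required, zero-count sites included); ``mode='field'`` fits a
    zero-truncated binomial null to the sites with at least one detection.
    """
    if history.n_visits < 2:
        raise ValueError("heterogeneity test is undefined for N=1 visit")
    y = history.require_complete()
    N = history.n_visits
    D = y.sum(axis=1)
    if mode == "simulated":
        if history.z is None:
            raise ValueError("simulated mode requires per-site truth flags")
        D_use = D[history.z]
        p_hat = fit_binomial_null(D_use, N)
        pmf = stats.binom.pmf(np.arange(N + 1), N, p_hat)
        observed = np.bincount(D_use, minlength=N + 1)
        d_offset = 0
    elif mode == "field":
        D_use = D[D >= 1]
        if len(D_use) < 2:
            raise ValueError("field mode needs at least 2 sites with detections")
        p_hat = fit_ztb_null(D_use, N)
        pmf = ztb_pmf(p_hat, N)
        observed = np.bincount(D_use, minlength=N + 1)[1:]
        d_offset = 1
    else:
        raise ValueError(f"mode must be 'simulated' or 'field', got {mode!r}")
    m_use = len(D_use)
    # the multinomial test samples from the fitted null pmf itself (rounding
    # small cells to zero would corrupt the null); the integer-repaired table
    # is the Fisher test's second row and the reported expected counts
    expected = largest_remainder_round(pmf * m_use, m_use)
    p, mc_err, used = _run_exact(observed, pmf * m_use, expected, rng,
                                 method, n_mc, alpha)
    return TestResult(
        name=f"heterogeneity_{mode}", observed=observed, expected=expected,
        p_value=p, mc_error=mc_err, n_mc=used, flagged=p < alpha,
        d_offset=d_offset, null_params={"p": p_hat, "method": method},
    )


def gof_test(
    fit: ModelFit,
    history: DetectionHistory,
    rng: np.random.Generator,
    alpha: float = ALPHA,
    n_mc: int = DEFAULT_N_MC,
    method: str = "fisher",
) -> TestResult:
    """Exact goodness-of-fit test of a fitted model on all M sites."""
    y = history.require_complete()
    N = history.n_visits
    M = history.n_sites
    observed = np.bincount(y.sum(axis=1), minlength=N + 1)
    expected_float = expected_distribution(fit, M, N)
    expected = largest_remainder_round(expected_float, M)
    p, mc_err, used = _run_exact(observed, expected_float, expected, rng,
                                 method, n_mc, alpha)
    return TestResult(
        name=f"gof_{fit.model}", observed=observed, expected=expected,
        p_value=p, mc_error=mc_err, n_mc=used, flagged=p < alpha,
        null_params={"model": fit.model, "psi_hat": fit.psi_hat,
                     "method": method},
    )
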