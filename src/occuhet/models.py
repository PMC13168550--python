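"""Covariate-free maximum-likelihood occupancy models.

Three single-season models for M x N detection-nondetection matrices,
each depending on the data only through the per-site detection counts
``D_i = sum_j y_ij``:

* **basic** -- zero-inflated binomial: ``D_i ~ ZIBinom(N, p, 1-psi)``;
  constant detection probability at occupied sites.
* **ZIBB** -- zero-inflated beta-binomial: site detection probability
  ``p_i ~ Beta(alpha, beta)``, integrated out analytically, so
  ``D_i | occupied ~ BetaBinom(N, alpha, beta)``.
* **RN** -- Royle-Nichols: latent site abundance ``B_i ~ Poisson(lambda)``
  with per-individual detection ``r``, so ``p_i = 1 - (1-r)**B_i``; occupancy
  is derived as ``psi = 1 - exp(-lambda)`` (probability a site has at least
  one individual).  The Poisson sum is truncated at K and K doubles
  automatically if tail mass remains.

All models are fit by quasi-Newton optimization on an unconstrained
transformed scale (logits for probabilities, logs for positive parameters)
with seeded random restarts; standard errors come from the inverse of a
finite-difference Hessian at the optimum.  Estimated occupancy above 0.99 is
flagged as a boundary estimate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Union

import numpy as np
from scipy import optimize, special, stats

from .simulate import DetectionHistory, DegenerateHistoryError

__all__ = [
    "BasicFit", "ZIBBFit", "RNFit", "ModelFit",
    "loglik_basic", "fit_basic", "fit_zibb", "fit_rn",
    "expected_distribution", "wald_ci", "fit_model",
]

BOUNDARY_PSI = 0.99
_LOGIT_CLIP = 500.0


def _expit(x):
    return special.expit(np.clip(x, -_LOGIT_CLIP, _LOGIT_CLIP))


def _counts(D: np.ndarray, n_visits: int) -> np.ndarray:
    """Tabulate detection counts into frequencies over D in {0..N}."""
    D = np.asarray(D, dtype=int)
    if D.min() < 0 or D.max() > n_visits:
        raise ValueError("detection counts must lie in [0, N]")
    return np.bincount(D, minlength=n_visits + 1).astype(float)


@dataclass
class _FitBase:
    psi_hat: float
    loglik: float
    converged: bool
    boundary: bool
    n_sites: int
    n_visits: int
    #: MLE on the unconstrained scale (see each model's parameterization)
    params_transformed: np.ndarray = field(repr=False, default=None)
    #: SEs on the same transformed scale; NaN where the Hessian was singular
    se_transformed: np.ndarray = field(repr=False, default=None)

    @property
    def se_available(self) -> bool:
        return self.se_transformed is not None and np.isfinite(self.se_transformed).all()

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("params_transformed", "se_transformed"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        d["model"] = self.model
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class BasicFit(_FitBase):
    """Zero-inflated binomial fit; transformed scale (logit psi, logit p)."""

    p_hat: float = np.nan
    model: str = "basic"

    @property
    def se_logit_psi(self) -> float:
        return float(self.se_transformed[0])

    @property
    def se_logit_p(self) -> float:
        return float(self.se_transformed[1])


@dataclass
class ZIBBFit(_FitBase):
    """Zero-inflated beta-binomial fit; scale (logit psi, log alpha, log beta)."""

    alpha_hat: float = np.nan
    beta_hat: float = np.nan
    model: str = "zibb"

    @property
    def mean_p(self) -> float:
        """Mean of the fitted site detection-probability distribution."""
        return self.alpha_hat / (self.alpha_hat + self.beta_hat)


@dataclass
class RNFit(_FitBase):
    """Royle-Nichols fit; scale (log lambda, logit r); psi derived from lambda."""

    lambda_hat: float = np.nan
    r_hat: float = np.nan
    K: int = 0
    model: str = "rn"


ModelFit = Union[BasicFit, ZIBBFit, RNFit]


# ---------------------------------------------------------------------------
# Log-likelihoods on count frequencies
# ---------------------------------------------------------------------------

def _zi_loglik_from_cell_logpmf(counts: np.ndarray, psi: float,
                                occ_logpmf: np.ndarray) -> float:
    """Sum of a zero-inflated mixture log-likelihood over tabulated counts.

    ``occ_logpmf[d]`` is log P(D=d | occupied); unoccupied sites contribute a
    point mass at zero with weight ``1 - psi``.
    """
    if not 0.0 <= psi <= 1.0:
        return -np.inf
    with np.errstate(divide="ignore"):
        cell = np.log(psi) + occ_logpmf
        cell[0] = np.logaddexp(cell[0], np.log1p(-psi) if psi < 1 else -np.inf)
    if np.any(counts[np.isneginf(cell)] > 0):
        return -np.inf
    mask = counts > 0
    return float(np.dot(counts[mask], cell[mask]))


def _binom_logpmf(n_visits: int, p: float) -> np.ndarray:
    d = np.arange(n_visits + 1)
    return stats.binom.logpmf(d, n_visits, p)


def loglik_basic(psi: float, p: float, D: np.ndarray, n_visits: int) -> float:
    """Zero-inflated binomial log-likelihood of the count vector D.

    Returns -inf (never raises) for parameters outside [0, 1].
    """
    if not (0.0 <= psi <= 1.0 and 0.0 <= p <= 1.0):
        return -np.inf
    counts = _counts(D, n_visits)
    return _zi_loglik_from_cell_logpmf(counts, psi, _binom_logpmf(n_visits, p))


def _betabinom_logpmf(n_visits: int, alpha: float, beta: float) -> np.ndarray:
    d = np.arange(n_visits + 1)
    return (
        special.gammaln(n_visits + 1)
        - special.gammaln(d + 1)
        - special.gammaln(n_visits - d + 1)
        + special.betaln(d + alpha, n_visits - d + beta)
        - special.betaln(alpha, beta)
    )


def loglik_zibb(psi: float, alpha: float, beta: float, D: np.ndarray,
                n_visits: int) -> float:
    """Zero-inflated beta-binomial log-likelihood of the count vector D."""
    if not 0.0 <= psi <= 1.0 or alpha <= 0 or beta <= 0:
        return -np.inf
    counts = _counts(D, n_visits)
    return _zi_loglik_from_cell_logpmf(
        counts, psi, _betabinom_logpmf(n_visits, alpha, beta)
    )


def _rn_logpmf(n_visits: int, lam: float, r: float, K: int) -> np.ndarray:
    """Marginal log pmf of D under Royle-Nichols, truncating B at K."""
    b = np.arange(K + 1)
    d = np.arange(n_visits + 1)
    log_pois = stats.poisson.logpmf(b, lam)
    with np.errstate(divide="ignore"):
        log_q = b * np.log1p(-r) if r < 1 else np.where(b > 0, -np.inf, 0.0)
        log_p = np.log1p(-np.exp(log_q))          # log p_i = log(1-(1-r)^B)
    log_p[0] = -np.inf                            # B=0: no detections possible
    log_q[0] = 0.0
    coef = (special.gammaln(n_visits + 1) - special.gammaln(d + 1)
            - special.gammaln(n_visits - d + 1))
    # matrix over (d, B); exponents of zero contribute 0 even against -inf
    with np.errstate(invalid="ignore"):
        succ = np.where(d[:, None] > 0, d[:, None] * log_p[None, :], 0.0)
        fail = np.where((n_visits - d)[:, None] > 0,
                        (n_visits - d)[:, None] * log_q[None, :], 0.0)
    m = log_pois[None, :] + succ + fail
    m[np.isnan(m)] = -np.inf
    return coef + special.logsumexp(m, axis=1)


def loglik_rn(lam: float, r: float, D: np.ndarray, n_visits: int,
              K: int = 60) -> float:
    """Royle-Nichols marginal log-likelihood with Poisson truncation at K."""
    if lam < 0 or not 0.0 <= r <= 1.0:
        return -np.inf
    counts = _counts(D, n_visits)
    cell = _rn_logpmf(n_visits, lam, r, K)
    if np.any(counts[np.isneginf(cell)] > 0):
        return -np.inf
    mask = counts > 0
    return float(np.dot(counts[mask], cell[mask]))


# ---------------------------------------------------------------------------
# Fitting machinery
# ---------------------------------------------------------------------------

def _maximize(nll, x0_list, tol=1e-10):
    best = None
    for x0 in x0_list:
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options={"ftol": tol, "gtol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    return best


def _fd_hessian(f, x, rel_step=1e-4):
    """Central finite-difference Hessian (few parameters, smooth objective)."""
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def _se_from_hessian(nll, x):
    try:
        H = _fd_hessian(nll, x)
        cov = np.linalg.inv(H)
        var = np.diag(cov)
        if np.any(var <= 0) or not np.isfinite(var).all():
            return np.full(len(x), np.nan)
        return np.sqrt(var)
    except (np.linalg.LinAlgError, FloatingPointError):
        return np.full(len(x), np.nan)


def _restarts(x0: np.ndarray, n: int, rng: np.random.Generator,
              scale: float = 2.0) -> list[np.ndarray]:
    return [x0] + [x0 + rng.normal(0.0, scale, size=len(x0)) for _ in range(n)]


def _history_counts(history: DetectionHistory):
    y = history.require_complete()
    D = y.sum(axis=1)
    return D, history.n_visits


def _as_counts(data, n_visits: Optional[int]):
    """Accept a DetectionHistory or a frequency vector over D in {0..N}.

    Frequency vectors may be non-integer (expected cell frequencies), which
    fits the model to an idealized distribution rather than a realized
    sample.
    """
    if isinstance(data, DetectionHistory):
        D, N = _history_counts(data)
        counts = _counts(D, N)
        n_visits = N
    else:
        counts = np.asarray(data, dtype=float)
        if counts.ndim != 1 or np.any(counts < 0):
            raise ValueError("counts must be a nonnegative vector over D in {0..N}")
        if n_visits is None:
            n_visits = len(counts) - 1
        elif len(counts) != n_visits + 1:
            raise ValueError("counts must have n_visits + 1 entries")
    if counts[1:].sum() == 0:
        raise DegenerateHistoryError("no detections in history: occupancy and "
                                     "detection are not separately identifiable")
    if counts[:-1].sum() == 0:
        raise DegenerateHistoryError("every site was detected on every visit: "
                                     "the model is degenerate")
    return counts, n_visits


def fit_basic(history, n_visits: Optional[int] = None, n_restarts: int = 5,
              seed: int = 0) -> BasicFit:
    """Fit the zero-inflated binomial ("basic") occupancy model by ML.

    ``history`` is a :class:`DetectionHistory` or a (possibly non-integer)
    frequency vector over D in {0..N} (then ``n_visits`` = len - 1).
    """
    counts, N = _as_counts(history, n_visits)
    if N < 2:
        raise ValueError("basic model needs at least 2 visits per site")
    naive = float(counts[1:].sum() / counts.sum())
    d = np.arange(N + 1)
    p0 = min(max((d * counts)[1:].sum() / (counts[1:].sum() * N), 0.05), 0.95)
    x0 = np.array([special.logit(min(max(naive, 0.05), 0.95)),
                   special.logit(p0)])

    def nll(x):
        return -_zi_loglik_from_cell_logpmf(
            counts, float(_expit(x[0])), _binom_logpmf(N, float(_expit(x[1])))
        )

    rng = np.random.default_rng(seed)
    res = _maximize(nll, _restarts(x0, n_restarts, rng))
    psi_hat, p_hat = float(_expit(res.x[0])), float(_expit(res.x[1]))
    if not res.success:
        warnings.warn("basic fit did not converge; best point returned",
                      RuntimeWarning)
    return BasicFit(
        psi_hat=psi_hat, p_hat=p_hat, loglik=-res.fun, converged=bool(res.success),
        boundary=psi_hat > BOUNDARY_PSI, n_sites=int(round(counts.sum())),
        n_visits=N,
        params_transformed=res.x, se_transformed=_se_from_hessian(nll, res.x),
    )


def fit_zibb(history, n_visits: Optional[int] = None, n_restarts: int = 5,
             seed: int = 0) -> ZIBBFit:
    """Fit the zero-inflated beta-binomial occupancy model by ML.

    With only 2 visits the three parameters are weakly identified; the fit is
    still attempted with a warning.  Accepts a history or a frequency vector
    like :func:`fit_basic`.
    """
    counts, N = _as_counts(history, n_visits)
    if N < 2:
        raise ValueError("ZIBB model needs at least 2 visits per site")
    if N == 2:
        warnings.warn("ZIBB with N=2 visits is weakly identified (3 parameters, "
                      "3 cells)", RuntimeWarning)
    naive = float(counts[1:].sum() / counts.sum())
    x0 = np.array([special.logit(min(max(naive, 0.05), 0.95)), 0.0, 0.0])

    def nll(x):
        a = np.exp(np.clip(x[1], -20.0, 20.0))
        b = np.exp(np.clip(x[2], -20.0, 20.0))
        return -_zi_loglik_from_cell_logpmf(
            counts, float(_expit(x[0])), _betabinom_logpmf(N, a, b)
        )

    rng = np.random.default_rng(seed)
    starts = _restarts(x0, n_restarts, rng)
    # high-concentration start near the binomial sub-model, so homogeneous
    # data cannot fit worse under ZIBB than under the nested basic model
    d = np.arange(N + 1)
    p_bar = min(max((d * counts)[1:].sum()
                    / max(counts[1:].sum(), 1.0) / N, 0.02), 0.98)
    conc = 1e7
    starts.append(np.array([x0[0], np.log(conc * p_bar),
                            np.log(conc * (1 - p_bar))]))
    res = _maximize(nll, starts)
    psi_hat = float(_expit(res.x[0]))
    alpha_hat = float(np.exp(np.clip(res.x[1], -20.0, 20.0)))
    beta_hat = float(np.exp(np.clip(res.x[2], -20.0, 20.0)))
    if not res.success:
        warnings.warn("ZIBB fit did not converge; best point returned",
                      RuntimeWarning)
    return ZIBBFit(
        psi_hat=psi_hat, alpha_hat=alpha_hat, beta_hat=beta_hat,
        loglik=-res.fun, converged=bool(res.success),
        boundary=psi_hat > BOUNDARY_PSI, n_sites=int(round(counts.sum())),
        n_visits=N,
        params_transformed=res.x, se_transformed=_se_from_hessian(nll, res.x),
    )


def fit_rn(history, n_visits: Optional[int] = None, K: int = 60,
           n_restarts: int = 5, seed: int = 0, _max_doublings: int = 6) -> RNFit:
    """Fit the Royle-Nichols abundance model by ML.

    The latent-abundance sum is truncated at ``K``; if the Poisson tail beyond
    K at the fitted lambda exceeds 1e-8, K doubles and the model refits.
    Accepts a history or a frequency vector like :func:`fit_basic`.
    """
    if K < 1:
        raise ValueError("truncation K must be >= 1")
    counts, N = _as_counts(history, n_visits)
    naive = float(counts[1:].sum() / counts.sum())
    lam0 = -np.log1p(-min(max(naive, 0.05), 0.95))
    x0 = np.array([np.log(lam0), special.logit(0.3)])

    rng = np.random.default_rng(seed)
    for _ in range(_max_doublings):
        def nll(x, K=K):
            lam = np.exp(np.clip(x[0], -20.0, 10.0))
            r = float(_expit(x[1]))
            cell = _rn_logpmf(N, lam, r, K)
            if np.any(counts[np.isneginf(cell)] > 0):
                return np.inf
            mask = counts > 0
            return -float(np.dot(counts[mask], cell[mask]))

        res = _maximize(nll, _restarts(x0, n_restarts, rng))
        lam_hat = float(np.exp(np.clip(res.x[0], -20.0, 10.0)))
        if stats.poisson.sf(K, lam_hat) <= 1e-8:
            break
        warnings.warn(f"RN truncation K={K} too small at lambda={lam_hat:.3g}; "
                      "doubling K", RuntimeWarning)
        K *= 2
    r_hat = float(_expit(res.x[1]))
    psi_hat = float(-np.expm1(-lam_hat))
    if not res.success:
        warnings.warn("RN fit did not converge; best point returned",
                      RuntimeWarning)
    return RNFit(
        psi_hat=psi_hat, lambda_hat=lam_hat, r_hat=r_hat, K=K,
        loglik=-res.fun, converged=bool(res.success),
        boundary=psi_hat > BOUNDARY_PSI, n_sites=int(round(counts.sum())),
        n_visits=N,
        params_transformed=res.x, se_transformed=_se_from_hessian(nll, res.x),
    )


_FITTERS = {"basic": fit_basic, "zibb": fit_zibb, "rn": fit_rn}


def fit_model(model: str, history: DetectionHistory, **kwargs) -> ModelFit:
    """Fit one of the three models by name ('basic', 'zibb', 'rn')."""
    try:
        fitter = _FITTERS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(_FITTERS)}")
    return fitter(history, **kwargs)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def model_pmf(fit: ModelFit, n_visits: int) -> np.ndarray:
    """Marginal pmf of D in {0..N} under the fitted model (all sites)."""
    if isinstance(fit, BasicFit):
        log_cell = _binom_logpmf(n_visits, fit.p_hat)
        psi = fit.psi_hat
    elif isinstance(fit, ZIBBFit):
        log_cell = _betabinom_logpmf(n_visits, fit.alpha_hat, fit.beta_hat)
        psi = fit.psi_hat
    elif isinstance(fit, RNFit):
        # RN's Poisson mixture already includes the unoccupied (B=0) sites
        pmf = np.exp(_rn_logpmf(n_visits, fit.lambda_hat, fit.r_hat, fit.K))
        return pmf / pmf.sum()
    else:
        raise TypeError(f"unsupported fit type {type(fit)}")
    pmf = psi * np.exp(log_cell)
    pmf[0] += 1.0 - psi
    return pmf / pmf.sum()


def expected_distribution(fit: ModelFit, n_sites: int, n_visits: int) -> np.ndarray:
    """Expected number of sites at each detection count D in {0..N}."""
    if not fit.converged:
        warnings.warn("expected distribution from a non-converged fit",
                      RuntimeWarning)
    return n_sites * model_pmf(fit, n_visits)


def wald_ci(fit: ModelFit, level: float = 0.95) -> Optional[tuple[float, float]]:
    """Wald confidence interval for occupancy, back-transformed to [0, 1].

    Built on logit psi for the basic and ZIBB models and on log lambda for
    Royle-Nichols (occupancy is a monotone function of lambda).  Returns
    ``None`` when the Hessian-based SE is unavailable.
    """
    if not fit.se_available:
        return None
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    x = fit.params_transformed[0]
    se = fit.se_transformed[0]
    lo, hi = x - zcrit * se, x + zcrit * se
    if isinstance(fit, RNFit):
        lam_lo = np.exp(np.clip(lo, -50, 50))
        lam_hi = np.exp(np.clip(hi, -50, 50))
        return (float(-np.expm1(-lam_lo)), float(-np.expm1(-lam_hi)))
    return (float(_expit(lo)), float(_expit(hi)))
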