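"""Five estimators for the canopy light extinction coefficient.

All methods share the saturating-exponential mean curve
``fPARi = 1 - exp(-k_j * LAI)`` with one coefficient per genotype:

* ``fit_lse``        — nonlinear least squares (point estimates only);
* ``fit_mle_normal`` — maximum likelihood with a normal response;
* ``fit_mle_beta``   — maximum likelihood with a beta (mean-precision) response;
* ``fit_logtlm``     — through-origin linear regression of log(1 - fPARi) on LAI;
* ``run_metropolis`` + ``summarize_posterior`` — Bayesian fit of the beta model
  with uniform priors on each k and a gamma prior on the precision.

The likelihood fits optimize jointly over (k_1..k_J, log dispersion) with the
dispersion shared across genotypes; standard errors come from the inverse of a
central finite-difference Hessian of the negative log-likelihood and 95%
intervals are Wald-type. The Bayesian sampler is a component-wise random-walk
Metropolis on (k_1..k_J, log kappa) with the log-scale Jacobian included.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import digamma, gammaln

from .data_io import Dataset
from .errors import ConfigurationError, DomainError, NumericError, ValidationError

#: Canonical method tags, in presentation order.
METHODS = ("LSE", "MLE_normal", "MLE_beta", "LogTLM", "Bayes_beta")

#: Two-sided 95% normal quantile used for Wald intervals.
WALD_Z = 1.959964


# ---------------------------------------------------------------------------
# mean curve and objective functions
# ---------------------------------------------------------------------------


def beer_lambert_mean(k, lai):
    """Expected intercepted fraction ``1 - exp(-k * lai)``.

    Vectorized over both arguments; values lie in [0, 1) for k, lai >= 0.
    """
    k = np.asarray(k, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if np.any(lai < 0):
        raise DomainError("lai must be >= 0")
    out = -np.expm1(-k * lai)
    if out.ndim == 0:
        return float(out)
    return out


def _unpack(d: Dataset):
    if d.n_obs == 0:
        raise ValidationError("empty dataset")
    lai, y, codes = d.to_arrays()
    return d.genotypes, lai, y, codes


def _check_k_vector(k_vector, J: int) -> np.ndarray:
    k = np.asarray(k_vector, dtype=float).ravel()
    if k.size != J:
        raise ConfigurationError(
            f"k_vector has length {k.size} but the dataset has {J} genotypes"
        )
    return k


def sse(k_vector, d: Dataset) -> float:
    """Sum of squared errors of the mean curve over all observations."""
    genotypes, lai, y, codes = _unpack(d)
    k = _check_k_vector(k_vector, len(genotypes))
    mu = -np.expm1(-k[codes] * lai)
    return float(np.sum((y - mu) ** 2))


def normal_loglik(k_vector, sigma2: float, d: Dataset) -> float:
    """Gaussian log-likelihood of the observations around the mean curve."""
    if not sigma2 > 0:
        raise DomainError("sigma2 must be > 0")
    genotypes, lai, y, codes = _unpack(d)
    k = _check_k_vector(k_vector, len(genotypes))
    mu = -np.expm1(-k[codes] * lai)
    n = y.size
    rss = np.sum((y - mu) ** 2)
    return float(-0.5 * n * np.log(2.0 * np.pi * sigma2) - rss / (2.0 * sigma2))


def _beta_logpdf_terms(y: np.ndarray, mu: np.ndarray, kappa: float) -> np.ndarray:
    """Per-observation beta log-density with shapes (mu*kappa, (1-mu)*kappa)."""
    a = mu * kappa
    b = (1.0 - mu) * kappa
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (
            gammaln(kappa)
            - gammaln(a)
            - gammaln(b)
            + (a - 1.0) * np.log(y)
            + (b - 1.0) * np.log1p(-y)
        )
    return np.where(np.isfinite(terms), terms, -np.inf)


def beta_loglik(k_vector, kappa: float, d: Dataset) -> float:
    """Beta log-likelihood (mean-precision shapes) around the mean curve."""
    if not kappa > 0:
        raise DomainError("kappa must be > 0")
    genotypes, lai, y, codes = _unpack(d)
    if np.any(y <= 0) or np.any(y >= 1):
        raise DomainError("beta likelihood requires all fpari strictly in (0, 1)")
    k = _check_k_vector(k_vector, len(genotypes))
    mu = -np.expm1(-k[codes] * lai)
    if np.any(mu <= 0) or np.any(mu >= 1):
        return -np.inf
    return float(np.sum(_beta_logpdf_terms(y, mu, kappa)))


# ---------------------------------------------------------------------------
# results and optimizer plumbing
# ---------------------------------------------------------------------------


@dataclass
class OptimizerConfig:
    """Multi-start quasi-Newton settings.

    Starting values for every k are drawn uniformly from
    (``start_low``, ``start_high``); the dispersion start is a
    method-of-moments value from the residuals of a least-squares pre-fit.
    """

    algorithm: str = "BFGS"
    n_starts: int = 10
    start_low: float = 0.2
    start_high: float = 0.8
    seed: int = 0
    tolerance: float = 1e-10
    shared_dispersion: bool = True

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ConfigurationError("n_starts must be >= 1")
        if not self.start_low < self.start_high:
            raise ConfigurationError("start_low must be < start_high")

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "n_starts": self.n_starts,
            "start_low": self.start_low,
            "start_high": self.start_high,
            "seed": self.seed,
            "tolerance": self.tolerance,
            "shared_dispersion": self.shared_dispersion,
        }


@dataclass
class FitResult:
    """Per-genotype estimates with (method-dependent) uncertainty.

    ``k_se`` and ``k_interval`` are ``None`` for LSE, which by construction
    carries no uncertainty measures; ``sse`` replaces ``loglik`` there.
    """

    method: str
    k_estimates: dict[str, float]
    k_se: dict[str, float] | None
    k_interval: dict[str, tuple[float, float]] | None
    dispersion_estimate: float | None
    loglik: float | None
    sse: float | None
    converged: bool
    n_obs: int
    n_genotypes: int
    config_echo: dict = field(default_factory=dict)

    @property
    def genotypes(self) -> list[str]:
        return list(self.k_estimates)

    def k_array(self, order: Sequence[str] | None = None) -> np.ndarray:
        order = list(self.k_estimates) if order is None else list(order)
        return np.array([self.k_estimates[g] for g in order], dtype=float)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "k_estimates": dict(self.k_estimates),
            "k_se": dict(self.k_se) if self.k_se is not None else None,
            "k_interval": {g: list(iv) for g, iv in self.k_interval.items()}
            if self.k_interval is not None
            else None,
            "dispersion_estimate": self.dispersion_estimate,
            "loglik": self.loglik,
            "sse": self.sse,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_genotypes": self.n_genotypes,
            "config_echo": self.config_echo,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def numeric_hessian(objective: Callable, point, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian, symmetrized as (H + H^T) / 2.

    ``step`` is relative: coordinate i uses ``step * max(|x_i|, 1)``.
    """
    x = np.asarray(point, dtype=float).ravel()
    p = x.size
    h = step * np.maximum(np.abs(x), 1.0)
    H = np.empty((p, p))
    f0 = objective(x)
    if not np.isfinite(f0):
        raise NumericError("objective is non-finite at the expansion point")

    def f_at(dx):
        val = objective(x + dx)
        if not np.isfinite(val):
            bad = np.nonzero(dx)[0].tolist()
            raise NumericError(
                f"objective non-finite in stencil at offsets of coordinates {bad}"
            )
        return val

    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f_at(ei) - 2.0 * f0 + f_at(-ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f_at(ei + ej) - f_at(ei - ej) - f_at(-ei + ej) + f_at(-ei - ej)
            ) / (4.0 * h[i] * h[j])
    return (H + H.T) / 2.0


def _multistart_minimize(fun, jac, n_k: int, extra0: np.ndarray, cfg: OptimizerConfig):
    """Best-of-n_starts quasi-Newton minimization; k starts are random."""
    rng = np.random.default_rng(cfg.seed)
    best = None
    any_success = False
    for _ in range(cfg.n_starts):
        k0 = rng.uniform(cfg.start_low, cfg.start_high, size=n_k)
        x0 = np.concatenate([k0, extra0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(
                fun,
                x0,
                jac=jac,
                method=cfg.algorithm,
                options={"gtol": cfg.tolerance, "maxiter": 2000},
            )
        if np.isfinite(res.fun):
            # status 2 = precision loss: the line search hit float resolution,
            # which at a tight gtol still means a located optimum
            any_success = any_success or bool(res.success) or res.status == 2
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise NumericError("all optimizer starts returned non-finite objectives")
    return best, any_success


def _wald(k_hat: np.ndarray, se: np.ndarray):
    lo = k_hat - WALD_Z * se
    hi = k_hat + WALD_Z * se
    return lo, hi


def _hessian_se(neg_loglik, theta_hat: np.ndarray, n_k: int):
    """k standard errors from the inverse Hessian; None when not invertible."""
    try:
        H = numeric_hessian(neg_loglik, theta_hat)
        cov = np.linalg.inv(H)
        var_k = np.diag(cov)[:n_k]
        if np.any(var_k <= 0) or not np.all(np.isfinite(var_k)):
            raise np.linalg.LinAlgError("non-positive variance from Hessian inverse")
        return np.sqrt(var_k)
    except (np.linalg.LinAlgError, NumericError) as exc:
        warnings.warn(
            f"standard errors unavailable: Hessian could not be inverted ({exc})",
            RuntimeWarning,
            stacklevel=3,
        )
        return None


# ---------------------------------------------------------------------------
# least squares
# ---------------------------------------------------------------------------


def fit_lse(d: Dataset, cfg: OptimizerConfig | None = None) -> FitResult:
    """Nonlinear least squares: point estimates only, no uncertainty."""
    cfg = cfg or OptimizerConfig()
    genotypes, lai, y, codes = _unpack(d)
    J = len(genotypes)

    def fun(theta):
        mu = -np.expm1(-theta[codes] * lai)
        return np.sum((y - mu) ** 2)

    def jac(theta):
        e = np.exp(-theta[codes] * lai)
        resid = y - (1.0 - e)
        contrib = -2.0 * resid * lai * e
        return np.bincount(codes, weights=contrib, minlength=J)

    best, ok = _multistart_minimize(fun, jac, J, np.empty(0), cfg)
    k_hat = best.x
    return FitResult(
        method="LSE",
        k_estimates=dict(zip(genotypes, map(float, k_hat))),
        k_se=None,
        k_interval=None,
        dispersion_estimate=None,
        loglik=None,
        sse=float(best.fun),
        converged=ok,
        n_obs=d.n_obs,
        n_genotypes=J,
        config_echo={"optimizer": cfg.to_dict()},
    )


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------


def _lse_residual_moments(d: Dataset, cfg: OptimizerConfig):
    """(mu_hat, residual variance) at a least-squares pre-fit, for dispersion starts."""
    pre = fit_lse(d, OptimizerConfig(n_starts=min(3, cfg.n_starts), seed=cfg.seed))
    genotypes, lai, y, codes = _unpack(d)
    k = pre.k_array(genotypes)
    mu = -np.expm1(-k[codes] * lai)
    resid_var = float(np.var(y - mu))
    return mu, max(resid_var, 1e-8)


def _fit_likelihood(d, cfg, neg_funjac, extra0, dispersion_name):
    genotypes, lai, y, codes = _unpack(d)
    J = len(genotypes)
    fun = lambda th: neg_funjac(th)[0]
    jac = lambda th: neg_funjac(th)[1]
    best, ok = _multistart_minimize(fun, jac, J, extra0, cfg)
    theta_hat = best.x
    k_hat = theta_hat[:J]
    dispersion = float(np.exp(theta_hat[J]))
    se = _hessian_se(fun, theta_hat, J)
    if se is not None:
        lo, hi = _wald(k_hat, se)
        k_se = dict(zip(genotypes, map(float, se)))
        k_iv = {g: (float(a), float(b)) for g, a, b in zip(genotypes, lo, hi)}
    else:
        k_se, k_iv = None, None
    return FitResult(
        method="",
        k_estimates=dict(zip(genotypes, map(float, k_hat))),
        k_se=k_se,
        k_interval=k_iv,
        dispersion_estimate=dispersion,
        loglik=float(-best.fun),
        sse=None,
        converged=ok,
        n_obs=d.n_obs,
        n_genotypes=J,
        config_echo={"optimizer": cfg.to_dict(), "dispersion_name": dispersion_name},
    )


def _split_by_genotype(d: Dataset) -> list[Dataset]:
    subs = []
    for g in d.genotypes:
        obs = [o for o in d.observations if o.genotype == g]
        subs.append(Dataset(observations=obs, genotype_index={g: 1}))
    return subs


def _merge_per_genotype(fits: list[FitResult], method: str, d: Dataset) -> FitResult:
    merged = FitResult(
        method=method,
        k_estimates={},
        k_se={},
        k_interval={},
        dispersion_estimate=None,
        loglik=0.0,
        sse=None,
        converged=all(f.converged for f in fits),
        n_obs=d.n_obs,
        n_genotypes=d.n_genotypes,
        config_echo={"per_genotype": [f.config_echo for f in fits]},
    )
    dispersions = {}
    for f in fits:
        merged.k_estimates.update(f.k_estimates)
        if f.k_se is None:
            merged.k_se = None
            merged.k_interval = None
        elif merged.k_se is not None:
            merged.k_se.update(f.k_se)
            merged.k_interval.update(f.k_interval)
        merged.loglik += f.loglik
        dispersions.update({g: f.dispersion_estimate for g in f.k_estimates})
    merged.config_echo["dispersion_per_genotype"] = dispersions
    return merged


def fit_mle_normal(d: Dataset, cfg: OptimizerConfig | None = None) -> FitResult:
    """Normal-response maximum likelihood over (k_1..k_J, log sigma^2).

    Point estimates for k coincide with least squares; the variance MLE is
    SSE/n. Wald 95% intervals come from the inverse numeric Hessian.
    """
    cfg = cfg or OptimizerConfig()
    if not cfg.shared_dispersion and d.n_genotypes > 1:
        sub_cfg = OptimizerConfig(**{**cfg.to_dict(), "shared_dispersion": True})
        fits = [fit_mle_normal(s, sub_cfg) for s in _split_by_genotype(d)]
        return _merge_per_genotype(fits, "MLE_normal", d)

    genotypes, lai, y, codes = _unpack(d)
    J, n = len(genotypes), y.size
    _, resid_var = _lse_residual_moments(d, cfg)

    def neg_funjac(theta):
        k, t = theta[:J], theta[J]
        s2 = np.exp(t)
        e = np.exp(-k[codes] * lai)
        resid = y - (1.0 - e)
        rss = np.sum(resid**2)
        nll = 0.5 * n * np.log(2.0 * np.pi * s2) + rss / (2.0 * s2)
        g_k = np.bincount(codes, weights=-resid * lai * e, minlength=J) / s2
        g_t = 0.5 * n - rss / (2.0 * s2)
        return nll, np.concatenate([g_k, [g_t]])

    out = _fit_likelihood(d, cfg, neg_funjac, np.array([np.log(resid_var)]), "sigma2")
    out.method = "MLE_normal"
    return out


def fit_mle_beta(d: Dataset, cfg: OptimizerConfig | None = None) -> FitResult:
    """Beta-response maximum likelihood over (k_1..k_J, log kappa)."""
    cfg = cfg or OptimizerConfig()
    genotypes, lai, y, codes = _unpack(d)
    if np.any(y <= 0) or np.any(y >= 1):
        raise DomainError("beta likelihood requires all fpari strictly in (0, 1)")
    if not cfg.shared_dispersion and d.n_genotypes > 1:
        sub_cfg = OptimizerConfig(**{**cfg.to_dict(), "shared_dispersion": True})
        fits = [fit_mle_beta(s, sub_cfg) for s in _split_by_genotype(d)]
        return _merge_per_genotype(fits, "MLE_beta", d)

    J = len(genotypes)
    mu0, resid_var = _lse_residual_moments(d, cfg)
    kappa0 = float(np.clip(np.mean(mu0 * (1.0 - mu0)) / resid_var - 1.0, 0.5, 1e4))
    log_y, log_1my = np.log(y), np.log1p(-y)

    def neg_funjac(theta):
        k, t = theta[:J], theta[J]
        kappa = np.exp(t)
        e = np.exp(-k[codes] * lai)
        mu = 1.0 - e
        if np.any(mu <= 0.0) or np.any(mu >= 1.0) or not np.isfinite(kappa):
            return np.inf, np.full(J + 1, np.nan)
        a, b = mu * kappa, (1.0 - mu) * kappa
        ll = np.sum(
            gammaln(kappa) - gammaln(a) - gammaln(b)
            + (a - 1.0) * log_y + (b - 1.0) * log_1my
        )
        if not np.isfinite(ll):
            return np.inf, np.full(J + 1, np.nan)
        dll_dmu = kappa * (-digamma(a) + digamma(b) + log_y - log_1my)
        dmu_dk = lai * e
        g_k = np.bincount(codes, weights=dll_dmu * dmu_dk, minlength=J)
        dll_dkappa = np.sum(
            digamma(kappa) - mu * digamma(a) - (1.0 - mu) * digamma(b)
            + mu * log_y + (1.0 - mu) * log_1my
        )
        grad = np.concatenate([g_k, [dll_dkappa * kappa]])
        return -ll, -grad

    out = _fit_likelihood(d, cfg, neg_funjac, np.array([np.log(kappa0)]), "kappa")
    out.method = "MLE_beta"
    return out


# ---------------------------------------------------------------------------
# log-transformed linear model
# ---------------------------------------------------------------------------


def fit_logtlm(d: Dataset) -> FitResult:
    """Through-origin least squares of log(1 - fPARi) on LAI, per genotype.

    The slope's negative is the k estimate: closed form, no optimizer.
    Standard errors and 95% intervals follow through-origin linear-model
    theory with the residual variance on the log scale (t quantile,
    n_j - 1 degrees of freedom).
    """
    genotypes, lai, y, codes = _unpack(d)
    if np.any(y >= 1):
        raise DomainError("log-transform requires fpari < 1 strictly")
    z = np.log1p(-y)
    k_est, k_se, k_iv, log_var = {}, {}, {}, {}
    for j, g in enumerate(genotypes):
        m = codes == j
        n_j = int(np.sum(m))
        if n_j < 2:
            raise ValidationError(
                f"genotype {g!r} has {n_j} observation(s); at least 2 required"
            )
        x_j, z_j = lai[m], z[m]
        sxx = float(np.sum(x_j**2))
        slope = float(np.sum(x_j * z_j) / sxx)
        resid = z_j - slope * x_j
        s2 = float(np.sum(resid**2) / (n_j - 1))
        se = float(np.sqrt(s2 / sxx))
        tq = float(stats.t.ppf(0.975, n_j - 1))
        k_hat = -slope
        k_est[g] = k_hat
        k_se[g] = se
        k_iv[g] = (k_hat - tq * se, k_hat + tq * se)
        log_var[g] = s2
    return FitResult(
        method="LogTLM",
        k_estimates=k_est,
        k_se=k_se,
        k_interval=k_iv,
        dispersion_estimate=None,
        loglik=None,
        sse=None,
        converged=True,
        n_obs=d.n_obs,
        n_genotypes=len(genotypes),
        config_echo={"log_scale_residual_variance": log_var},
    )


# ---------------------------------------------------------------------------
# Bayesian estimation
# ---------------------------------------------------------------------------


@dataclass
class PriorSpec:
    """Weakly informative priors: uniform on each k, gamma (shape-rate) on kappa."""

    k_low: float = 0.0
    k_high: float = 2.0
    kappa_shape: float = 24.0
    kappa_rate: float = 2.0

    def __post_init__(self) -> None:
        if not self.k_low < self.k_high:
            raise ConfigurationError("k prior needs low < high")
        if not (self.kappa_shape > 0 and self.kappa_rate > 0):
            raise ConfigurationError("gamma prior needs shape, rate > 0")

    def to_dict(self) -> dict:
        return {
            "k_prior": ["uniform", self.k_low, self.k_high],
            "dispersion_prior": ["gamma_shape_rate", self.kappa_shape, self.kappa_rate],
        }


def log_posterior(k_vector, kappa: float, d: Dataset, priors: PriorSpec | None = None) -> float:
    """Unnormalized log posterior: beta log-likelihood plus log priors.

    Returns -inf (never raises) when any k is outside the uniform support or
    kappa <= 0. An empty dataset contributes zero likelihood, leaving the
    prior alone.
    """
    priors = priors or PriorSpec()
    k = np.asarray(k_vector, dtype=float).ravel()
    if np.any(k <= priors.k_low) or np.any(k >= priors.k_high) or not kappa > 0:
        return -np.inf
    lp = k.size * (-np.log(priors.k_high - priors.k_low))
    lp += float(
        stats.gamma.logpdf(kappa, a=priors.kappa_shape, scale=1.0 / priors.kappa_rate)
    )
    if d.n_obs > 0:
        lp += beta_loglik(k, kappa, d)
    return float(lp)


@dataclass
class MCMCConfig:
    """Random-walk Metropolis settings.

    Proposal scales are tuned during a pilot phase (discarded) toward a
    20-45% per-parameter acceptance window unless given explicitly.
    """

    n_iter: int = 20000
    n_burnin: int = 5000
    thin: int = 1
    seed: int = 0
    proposal_scales: np.ndarray | None = None
    pilot_rounds: int = 10
    pilot_len: int = 150

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ConfigurationError("n_burnin must be < n_iter")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_iter": self.n_iter,
            "n_burnin": self.n_burnin,
            "thin": self.thin,
            "seed": self.seed,
            "proposal_scales": None
            if self.proposal_scales is None
            else list(map(float, np.asarray(self.proposal_scales))),
            "pilot_rounds": self.pilot_rounds,
            "pilot_len": self.pilot_len,
        }


@dataclass
class PosteriorSamples:
    """Retained post-burn-in draws of (k_1..k_J, kappa)."""

    draws: np.ndarray
    genotypes: list[str]
    n_burnin: int
    n_iter: int
    thin: int
    acceptance_rate: float
    seed: int

    @property
    def param_names(self) -> list[str]:
        return [f"k:{g}" for g in self.genotypes] + ["kappa"]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def to_csv(self, path) -> None:
        header = ",".join(self.param_names)
        np.savetxt(path, self.draws, delimiter=",", header=header, comments="")


class _BetaTerms:
    """Per-genotype beta log-likelihood terms with caching for the sampler."""

    def __init__(self, d: Dataset):
        self.genotypes = d.genotypes
        self.lai, self.y, self.log_y, self.log_1my = [], [], [], []
        if d.n_obs:
            lai, y, codes = d.to_arrays()
            for j in range(len(self.genotypes)):
                m = codes == j
                self.lai.append(lai[m])
                self.y.append(y[m])
                self.log_y.append(np.log(y[m]))
                self.log_1my.append(np.log1p(-y[m]))
        else:
            for _ in self.genotypes:
                self.lai.append(np.empty(0))
                self.y.append(np.empty(0))
                self.log_y.append(np.empty(0))
                self.log_1my.append(np.empty(0))

    def term(self, j: int, k: float, kappa: float) -> float:
        lai = self.lai[j]
        if lai.size == 0:
            return 0.0
        mu = -np.expm1(-k * lai)
        if np.any(mu <= 0.0) or np.any(mu >= 1.0):
            return -np.inf
        a, b = mu * kappa, (1.0 - mu) * kappa
        val = np.sum(
            gammaln(kappa) - gammaln(a) - gammaln(b)
            + (a - 1.0) * self.log_y[j] + (b - 1.0) * self.log_1my[j]
        )
        return float(val) if np.isfinite(val) else -np.inf


def run_metropolis(
    d: Dataset,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
) -> PosteriorSamples:
    """Component-wise random-walk Metropolis on (k_1..k_J, log kappa).

    kappa is proposed on the log scale with the Jacobian term ``+log kappa``
    included in the target. Draws are fully reproducible from ``mcmc.seed``.
    A dataset with observations uses its genotype index; an empty dataset
    (prior-only sampling) must still carry an explicit genotype index.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or MCMCConfig()
    if d.n_genotypes == 0:
        raise ConfigurationError("dataset has no genotypes in its index")
    terms = _BetaTerms(d)
    J = len(terms.genotypes)
    rng = np.random.default_rng(mcmc.seed)

    def log_gamma_prior(kappa: float) -> float:
        return float(
            stats.gamma.logpdf(kappa, a=priors.kappa_shape, scale=1.0 / priors.kappa_rate)
        )

    # state
    k = np.full(J, 0.5 * (priors.k_low + priors.k_high))
    t = float(np.log(priors.kappa_shape / priors.kappa_rate))  # log kappa at prior mean
    kappa = float(np.exp(t))
    cur = np.array([terms.term(j, k[j], kappa) for j in range(J)])
    cur_kprior = log_gamma_prior(kappa) + t  # prior + Jacobian

    if mcmc.proposal_scales is not None:
        scales = np.asarray(mcmc.proposal_scales, dtype=float).copy()
        if scales.size != J + 1:
            raise ConfigurationError(f"proposal_scales must have length {J + 1}")
        tune = False
    else:
        scales = np.concatenate([np.full(J, 0.05), [0.3]])
        tune = True

    def sweep(count_acc=None):
        nonlocal k, t, kappa, cur, cur_kprior
        for j in range(J):
            prop = k[j] + scales[j] * rng.standard_normal()
            if priors.k_low < prop < priors.k_high:
                new = terms.term(j, prop, kappa)
                if np.log(rng.random()) < new - cur[j]:
                    k[j] = prop
                    cur[j] = new
                    if count_acc is not None:
                        count_acc[j] += 1
        t_prop = t + scales[J] * rng.standard_normal()
        kappa_prop = float(np.exp(t_prop))
        if kappa_prop > 0 and np.isfinite(kappa_prop):
            new_terms = np.array([terms.term(j, k[j], kappa_prop) for j in range(J)])
            new_kprior = log_gamma_prior(kappa_prop) + t_prop
            delta = np.sum(new_terms) + new_kprior - np.sum(cur) - cur_kprior
            if np.log(rng.random()) < delta:
                t, kappa = t_prop, kappa_prop
                cur = new_terms
                cur_kprior = new_kprior
                if count_acc is not None:
                    count_acc[J] += 1

    if tune:
        for _ in range(mcmc.pilot_rounds):
            acc = np.zeros(J + 1)
            for _ in range(mcmc.pilot_len):
                sweep(acc)
            rate = acc / mcmc.pilot_len
            scales[rate > 0.45] *= 1.7
            scales[rate < 0.20] /= 1.7

    draws = np.empty((mcmc.n_iter, J + 1))
    acc = np.zeros(J + 1)
    for i in range(mcmc.n_iter):
        sweep(acc)
        draws[i, :J] = k
        draws[i, J] = kappa
    retained = draws[mcmc.n_burnin :: mcmc.thin].copy()
    acceptance = float(np.sum(acc) / ((J + 1) * mcmc.n_iter))
    return PosteriorSamples(
        draws=retained,
        genotypes=list(terms.genotypes),
        n_burnin=mcmc.n_burnin,
        n_iter=mcmc.n_iter,
        thin=mcmc.thin,
        acceptance_rate=acceptance,
        seed=mcmc.seed,
    )


def summarize_posterior(s: PosteriorSamples, level: float = 0.95) -> FitResult:
    """Posterior means, SDs and equal-tailed credible intervals as a FitResult."""
    if s.n_draws == 0:
        raise ValidationError("no retained draws to summarize")
    if not 0 < level < 1:
        raise ConfigurationError("level must be in (0, 1)")
    J = len(s.genotypes)
    alpha = (1.0 - level) / 2.0
    k_draws = s.draws[:, :J]
    means = k_draws.mean(axis=0)
    sds = k_draws.std(axis=0, ddof=1) if s.n_draws > 1 else np.zeros(J)
    lo = np.quantile(k_draws, alpha, axis=0)
    hi = np.quantile(k_draws, 1.0 - alpha, axis=0)
    return FitResult(
        method="Bayes_beta",
        k_estimates=dict(zip(s.genotypes, map(float, means))),
        k_se=dict(zip(s.genotypes, map(float, sds))),
        k_interval={g: (float(a), float(b)) for g, a, b in zip(s.genotypes, lo, hi)},
        dispersion_estimate=float(s.draws[:, J].mean()),
        loglik=None,
        sse=None,
        converged=True,
        n_obs=0,
        n_genotypes=J,
        config_echo={
            "sampler": {
                "n_iter": s.n_iter,
                "n_burnin": s.n_burnin,
                "thin": s.thin,
                "acceptance_rate": s.acceptance_rate,
                "seed": s.seed,
            },
            "level": level,
        },
    )


def kde_mode(samples: np.ndarray, n_grid: int = 2001) -> float:
    """Argmax of a Gaussian kernel density estimate over the sample range."""
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValidationError("no samples")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), n_grid)
    return float(grid[int(np.argmax(kde(grid)))])
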