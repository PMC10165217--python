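"""Bayesian logistic regression under a diffuse normal prior and the
hyper-g prior.

Two priors are supported:

* ``normal`` -- independent N(0, v) on each coefficient (default v =
  100), the conventional weakly informative choice.
* ``hyper_g`` -- beta | g ~ N(nu, g * Sigma) with Sigma = diag(1/2) and
  the hyper-prior density f(g) = ((a-2)/2) (1+g)^(-a/2), g > 0, proper
  for a > 2.  At the default a = 4 the shrinkage factor g/(1+g) is
  uniform on (0, 1), the prior median of g is 1 and the CDF is
  F(g) = g/(1+g).

Posterior summaries are the per-coefficient median and equal-tailed 95%
credible interval.  Sampling is an adaptive random-walk Metropolis on
beta (proposal covariance from the penalized-likelihood curvature,
scale tuned during burn-in, frozen afterwards) with a stepping-out
slice-sampler update of log g for the hyper-g prior.  Chains are
reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .model_core import BinaryDataset, FitResult, InputError, _loglik_raw

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSummary",
    "hyper_g_prior_cdf",
    "sample_hyper_g_prior",
    "sample_posterior",
    "fit_bayes",
]


@dataclass
class PriorSpec:
    """Prior on the logistic coefficients.

    ``include_intercept`` controls whether the prior also covers the
    intercept (default True, reading the coefficient-vector prior
    literally); with False the intercept gets a flat prior.
    """

    kind: str = "normal"
    normal_variance: float = 100.0
    hg_sigma_diag: float = 0.5
    hg_a: float = 4.0
    mean: np.ndarray | None = None
    include_intercept: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "hyper_g"):
            raise InputError(f"unknown prior kind {self.kind!r}")
        if self.normal_variance <= 0 or self.hg_sigma_diag <= 0:
            raise InputError("prior variances must be positive")
        if self.kind == "hyper_g" and self.hg_a <= 2:
            raise InputError("hyper-g prior is improper for a <= 2")


@dataclass
class MCMCConfig:
    draws: int = 10_000
    burnin: int = 2_000
    chains: int = 4
    seed: int = 0
    ess_floor: float = 100.0

    @classmethod
    def from_file(cls, path: str) -> "MCMCConfig":
        """Load a chain configuration from a YAML or JSON file."""
        import json

        import yaml

        with open(path) as fh:
            cfg = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
        return cls(**cfg)


@dataclass
class PosteriorSummary:
    median: np.ndarray
    credible_low: np.ndarray
    credible_high: np.ndarray
    n_draws: int
    ess: np.ndarray
    seed: int
    accept_rate: float
    g_median: float | None = None
    low_ess_warning: bool = False

    def odds_ratio(self, j: int = 1) -> float:
        return float(np.exp(self.median[j]))


def hyper_g_prior_cdf(g: float, a: float = 4.0) -> float:
    """CDF of the hyper-g prior: 1 - (1+g)^(-(a-2)/2); g/(1+g) at a=4."""
    if a <= 2:
        raise InputError("hyper-g prior is improper for a <= 2")
    g = float(g)
    if g <= 0:
        return 0.0
    return 1.0 - (1.0 + g) ** (-(a - 2.0) / 2.0)


def sample_hyper_g_prior(n: int, a: float = 4.0, rng: np.random.Generator | None = None) -> np.ndarray:
    """Prior draws of g by CDF inversion (for prior-predictive checks)."""
    if a <= 2:
        raise InputError("hyper-g prior is improper for a <= 2")
    rng = np.random.default_rng() if rng is None else rng
    u = rng.uniform(size=n)
    return (1.0 - u) ** (-2.0 / (a - 2.0)) - 1.0


# ---------------------------------------------------------------------------
# Log posterior pieces
# ---------------------------------------------------------------------------

class _Posterior:
    def __init__(self, data: BinaryDataset | None, prior: PriorSpec, p: int):
        self.prior = prior
        self.p = p
        if data is None or data.n_records == 0:
            self.y = self.X = self.w = None
        else:
            self.y = data.outcome
            self.X = data.design_matrix()
            self.w = data.weights
        self.mean = np.zeros(p) if prior.mean is None else np.asarray(prior.mean, float)
        self.active = np.ones(p, dtype=bool)
        if not prior.include_intercept:
            self.active[0] = False

    def loglik(self, beta: np.ndarray) -> float:
        if self.y is None:
            return 0.0
        return _loglik_raw(self.y, self.X, self.w, beta)

    def log_prior_beta(self, beta: np.ndarray, g: float) -> float:
        d = (beta - self.mean)[self.active]
        if self.prior.kind == "normal":
            v = self.prior.normal_variance
        else:
            v = g * self.prior.hg_sigma_diag
        return float(-0.5 * np.sum(d * d) / v - 0.5 * d.size * math.log(v))

    def log_post(self, beta: np.ndarray, g: float) -> float:
        return self.loglik(beta) + self.log_prior_beta(beta, g)

    def log_post_g(self, log_g: float, beta: np.ndarray) -> float:
        # density of log g given beta: prior f(g) with Jacobian g, times
        # the normal kernel's g-dependent factor
        a = self.prior.hg_a
        d = (beta - self.mean)[self.active]
        S = float(np.sum(d * d)) / self.prior.hg_sigma_diag
        try:
            quad = -0.5 * S * math.exp(-log_g)
        except OverflowError:
            return -math.inf
        if quad == -math.inf or not math.isfinite(quad):
            return -math.inf
        return (
            -0.5 * d.size * log_g
            + quad
            - 0.5 * a * np.logaddexp(0.0, log_g)
            + log_g
        )


def _slice_sample(logf, x0: float, rng: np.random.Generator, w: float = 1.0, m: int = 50) -> float:
    """Univariate stepping-out slice sampler (Neal 2003)."""
    fx0 = logf(x0)
    logy = fx0 + math.log(rng.uniform())
    u = rng.uniform()
    L, R = x0 - w * u, x0 + w * (1.0 - u)
    j = int(rng.integers(0, m))
    k = m - 1 - j
    while j > 0 and logf(L) > logy:
        L -= w
        j -= 1
    while k > 0 and logf(R) > logy:
        R += w
        k -= 1
    for _ in range(1000):
        x1 = rng.uniform(L, R)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            L = x1
        else:
            R = x1
    return x0  # pragma: no cover - slice shrinkage exhausted


def _proposal_chol(post: _Posterior, beta0: np.ndarray, g0: float) -> np.ndarray:
    """Cholesky of an approximate posterior covariance for the proposal."""
    p = post.p
    prec = np.zeros((p, p))
    if post.y is not None:
        pi = special.expit(post.X @ beta0)
        W = post.w * pi * (1.0 - pi)
        prec += (post.X * W[:, None]).T @ post.X
    if post.prior.kind == "normal":
        v = post.prior.normal_variance
    else:
        # floor g so a transiently tiny draw cannot collapse the proposal
        v = max(g0, 1e-3) * post.prior.hg_sigma_diag
    prec[np.diag_indices(p)] += np.where(post.active, 1.0 / v, 1e-8)
    cov = np.linalg.inv(prec)
    # symmetrize against rounding
    cov = 0.5 * (cov + cov.T)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return np.diag(np.sqrt(np.clip(np.diag(cov), 1e-12, None)))


def _run_chain(post: _Posterior, cfg_draws: int, burnin: int, rng: np.random.Generator,
               beta0: np.ndarray) -> tuple[np.ndarray, np.ndarray | None, float]:
    p = post.p
    hyper = post.prior.kind == "hyper_g"
    g = 1.0
    beta = beta0.copy()
    chol = _proposal_chol(post, beta, g)
    log_scale = math.log(2.38 / math.sqrt(p))
    lp = post.log_post(beta, g)
    total = burnin + cfg_draws
    draws = np.empty((cfg_draws, p))
    gdraws = np.empty(cfg_draws) if hyper else None
    accepted = 0
    n_prop = 0
    for it in range(total):
        prop = beta + math.exp(log_scale) * (chol @ rng.standard_normal(p))
        lp_prop = post.log_post(prop, g)
        n_prop += 1
        accept = math.log(rng.uniform()) < lp_prop - lp
        if accept:
            beta, lp = prop, lp_prop
            accepted += 1
        if hyper:
            log_g = _slice_sample(lambda lg: post.log_post_g(lg, beta), math.log(g), rng)
            g = math.exp(log_g)
            lp = post.log_post(beta, g)
        if it < burnin:
            # Robbins-Monro tuning toward ~0.3 acceptance, frozen afterwards
            rate = 1.0 if accept else 0.0
            log_scale += (rate - 0.3) / (1.0 + 0.05 * it) * 0.5
            if it == burnin // 2:
                chol = _proposal_chol(post, beta, g)
        else:
            k = it - burnin
            draws[k] = beta
            if hyper:
                gdraws[k] = g
    return draws, gdraws, accepted / max(n_prop, 1)


def _ess(x: np.ndarray) -> float:
    """Effective sample size by the initial positive sequence estimator."""
    n = x.shape[0]
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        return float(n)
    acf_sum = 0.0
    for lag in range(1, min(n // 2, 1000)):
        rho = float(np.dot(x[:-lag], x[lag:])) / ((n - lag) * var)
        if rho <= 0.0:
            break
        acf_sum += rho
    return n / (1.0 + 2.0 * acf_sum)


def sample_posterior(
    data: BinaryDataset | None,
    prior: PriorSpec,
    mcmc: MCMCConfig,
    n_coef: int | None = None,
) -> PosteriorSummary:
    """Draw from p(beta | data) (jointly with g for the hyper-g prior)
    and summarize by the median and equal-tailed 95% credible interval.

    ``data=None`` (or an empty dataset) samples the prior itself, which
    requires ``n_coef``; useful for prior-recovery checks.
    """
    if data is None:
        if n_coef is None:
            raise InputError("n_coef is required when sampling without data")
        p = n_coef
    else:
        p = data.n_coef
    post = _Posterior(data, prior, p)
    if post.y is None and not prior.include_intercept and prior.kind != "normal":
        raise InputError("cannot sample a flat intercept prior without data")

    beta0 = np.zeros(p)
    if post.y is not None:
        # start at the Firth mode: always finite, close to the posterior bulk
        from .firth import fit_firth

        try:
            start = fit_firth(data)
            if start.converged:
                beta0 = start.estimate.copy()
        except InputError:
            pass

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    all_draws = []
    all_g = []
    acc = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        draws, gdraws, a = _run_chain(post, mcmc.draws, mcmc.burnin, rng, beta0)
        all_draws.append(draws)
        acc.append(a)
        if gdraws is not None:
            all_g.append(gdraws)
    pooled = np.concatenate(all_draws, axis=0)
    med = np.median(pooled, axis=0)
    lo = np.percentile(pooled, 2.5, axis=0)
    hi = np.percentile(pooled, 97.5, axis=0)
    ess = np.array([sum(_ess(d[:, j]) for d in all_draws) for j in range(p)])
    g_med = float(np.median(np.concatenate(all_g))) if all_g else None
    return PosteriorSummary(
        median=med,
        credible_low=lo,
        credible_high=hi,
        n_draws=pooled.shape[0],
        ess=ess,
        seed=mcmc.seed,
        accept_rate=float(np.mean(acc)),
        g_median=g_med,
        low_ess_warning=bool(np.any(ess < mcmc.ess_floor)),
    )


def fit_bayes(
    data: BinaryDataset,
    prior: PriorSpec,
    mcmc: MCMCConfig,
) -> FitResult:
    """Posterior sampling packaged as a FitResult (median point estimate,
    credible bounds in the interval fields)."""
    summary = sample_posterior(data, prior, mcmc)
    method = "NP" if prior.kind == "normal" else "HG"
    notes = ""
    if summary.low_ess_warning:
        notes = "low effective sample size"
    return FitResult(
        method=method,
        estimate=summary.median,
        interval_low=summary.credible_low,
        interval_high=summary.credible_high,
        loglik=float("nan"),
        converged=not summary.low_ess_warning,
        n_iter=summary.n_draws,
        notes=notes,
        term_names=data.term_names(),
    )
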