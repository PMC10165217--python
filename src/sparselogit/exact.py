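"""Exact conditional logistic inference.

For coefficient j the sufficient statistic is T_j = sum_i y_i x_ij.
Conditioning on the sufficient statistics of every other coefficient
(including the intercept's event total) leaves a one-parameter
exponential family on the integer support of T_j:

    Pr(T_j = t | beta_j)  proportional to  c(t) exp(beta_j t),

where c(t) counts the outcome permutations consistent with the
conditioning statistics.  The counts are computed exactly (integer
arithmetic) by dynamic programming over records; a record with integer
weight m is treated as m identical records through binomial
transitions, so grouped data give the same distribution as expanded
records.

The conditional MLE solves the tilted-mean equation; when the observed
statistic sits on the boundary of its support the median-unbiased
estimate (tail probability 1/2) is substituted.  Exact and mid-P
intervals invert the tail probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .model_core import BinaryDataset, FitResult, InputError

__all__ = [
    "ConditionalDistribution",
    "CapacityError",
    "DegenerateSupportError",
    "conditional_distribution",
    "conditional_mle",
    "exact_ci",
    "midp_ci",
    "fit_exact",
]

STATE_CAP = 50_000_000  # maximum number of live DP states


class CapacityError(RuntimeError):
    """Conditioning state space exceeds the configured cap."""


class DegenerateSupportError(RuntimeError):
    """The conditioning constraints force a unique outcome pattern;
    the coefficient is inestimable by exact conditioning."""


@dataclass
class ConditionalDistribution:
    """Support, exact permutation counts and the observed value of T_j."""

    support: np.ndarray          # sorted integer values of T_j
    counts: list                 # exact integer counts c(t), same order
    observed: int
    log_counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        if self.observed not in set(self.support.astype(int)):
            raise InputError("observed statistic not in support")
        if any(c < 1 for c in self.counts):
            raise InputError("permutation counts must be positive")
        # float log-counts for numerically stable tilting
        self.log_counts = np.array(
            [_log_bigint(c) for c in self.counts], dtype=float
        )

    def log_probs(self, beta: float) -> np.ndarray:
        lw = self.log_counts + beta * self.support
        return lw - special.logsumexp(lw)

    def probs(self, beta: float) -> np.ndarray:
        return np.exp(self.log_probs(beta))

    def tilted_mean(self, beta: float) -> float:
        return float(np.sum(self.probs(beta) * self.support))

    def tail_ge(self, beta: float) -> float:
        """Pr(T >= observed | beta)."""
        lp = self.log_probs(beta)
        mask = self.support >= self.observed
        return float(np.exp(special.logsumexp(lp[mask])))

    def tail_le(self, beta: float) -> float:
        lp = self.log_probs(beta)
        mask = self.support <= self.observed
        return float(np.exp(special.logsumexp(lp[mask])))

    def point_mass(self, beta: float) -> float:
        lp = self.log_probs(beta)
        idx = int(np.nonzero(self.support == self.observed)[0][0])
        return float(np.exp(lp[idx]))


def _log_bigint(c) -> float:
    c = int(c)
    # math.log handles arbitrarily large ints via frexp-style scaling
    nbits = c.bit_length()
    if nbits <= 900:
        return math.log(c)
    shift = nbits - 900
    return math.log(c >> shift) + shift * math.log(2.0)


# ---------------------------------------------------------------------------
# Dynamic programming over integer sufficient-statistic states
# ---------------------------------------------------------------------------

def conditional_distribution(
    data: BinaryDataset, j: int, state_cap: int = STATE_CAP
) -> ConditionalDistribution:
    """Exact permutational distribution of T_j given all other sufficient
    statistics (the intercept's event total is always conditioned on).

    ``j`` indexes the coefficient vector, so j >= 1 (the intercept has no
    conditional distribution of its own).  Covariates must be
    integer-valued and weights integer (group sizes).
    """
    if j < 1 or j >= data.n_coef:
        raise InputError("j must index a non-intercept coefficient")
    X = data.design_matrix()
    if not np.all(X == np.round(X)):
        raise InputError("exact conditional inference requires integer-valued covariates")
    w = data.weights
    if not np.all(w == np.round(w)):
        raise InputError("exact conditional inference requires integer weights (group sizes)")
    Xi = X.astype(np.int64)
    wi = w.astype(np.int64)
    y = data.outcome.astype(np.int64)

    p = data.n_coef
    cond_idx = [c for c in range(p) if c != j]
    # observed sufficient statistics
    t_all = (wi * y) @ Xi
    t_cond = tuple(int(t_all[c]) for c in cond_idx)
    t_obs = int(t_all[j])

    nonneg = bool(np.all(Xi >= 0))
    # remaining attainable increments for look-ahead pruning (nonneg case)
    rows = [(int(wi[i]), tuple(int(Xi[i, c]) for c in cond_idx), int(Xi[i, j]))
            for i in range(data.n_records) if wi[i] > 0]
    ncond = len(cond_idx)
    suffix_max = [None] * (len(rows) + 1)
    suffix_max[len(rows)] = (0,) * ncond
    for i in range(len(rows) - 1, -1, -1):
        wgt, xc, _ = rows[i]
        suffix_max[i] = tuple(
            suffix_max[i + 1][c] + max(0, xc[c]) * wgt for c in range(ncond)
        )

    # state: (cond stats..., t_j) -> exact integer count
    states: dict[tuple, int] = {(0,) * (ncond + 1): 1}
    for i, (wgt, xc, xj) in enumerate(rows):
        new: dict[tuple, int] = {}
        # binomial coefficients C(wgt, e), grown lazily: huge groups only
        # ever contribute up to the remaining event need
        binom = [1]
        for state, cnt in states.items():
            e_hi = wgt
            if nonneg:
                # a group of w identical records can contribute at most the
                # remaining need on every conditioning statistic it increments
                for c in range(ncond):
                    if xc[c] > 0:
                        room = (t_cond[c] - state[c]) // xc[c]
                        if room < e_hi:
                            e_hi = room
                if e_hi < 0:
                    continue
            for e in range(e_hi + 1):
                cond_new = tuple(state[c] + e * xc[c] for c in range(ncond))
                if nonneg:
                    ok = True
                    for c in range(ncond):
                        if cond_new[c] > t_cond[c]:
                            ok = False
                            break
                        if cond_new[c] + suffix_max[i + 1][c] < t_cond[c]:
                            ok = False
                            break
                    if not ok:
                        continue
                while e >= len(binom):
                    k = len(binom)
                    binom.append(binom[-1] * (wgt - k + 1) // k)
                key = cond_new + (state[ncond] + e * xj,)
                new[key] = new.get(key, 0) + cnt * binom[e]
        states = new
        if len(states) > state_cap:
            raise CapacityError(
                f"conditional state space exceeded the cap of {state_cap} states; "
                "reduce the sample size or the number of conditioning covariates"
            )

    dist: dict[int, int] = {}
    for state, cnt in states.items():
        if state[:ncond] == t_cond:
            tj = state[ncond]
            dist[tj] = dist.get(tj, 0) + cnt
    if not dist:
        raise InputError("observed conditioning statistics unreachable (internal error)")
    if len(dist) == 1:
        raise DegenerateSupportError(
            "conditioning constraints admit a single outcome pattern; "
            "the coefficient is inestimable"
        )
    support = sorted(dist)
    return ConditionalDistribution(
        support=np.array(support, dtype=float),
        counts=[dist[t] for t in support],
        observed=t_obs,
    )


# ---------------------------------------------------------------------------
# Point estimation and intervals
# ---------------------------------------------------------------------------

_BRACKET0 = 1.0


def _solve_monotone(f, target: float, increasing: bool, tol: float = 1e-10) -> float:
    """Root of f(beta) = target for monotone f, with geometric bracketing."""
    def g(b):
        return f(b) - target

    lo, hi = -_BRACKET0, _BRACKET0
    glo, ghi = g(lo), g(hi)
    sign = 1.0 if increasing else -1.0
    for _ in range(200):
        if sign * glo < 0:
            break
        lo *= 2.0
        glo = g(lo)
    for _ in range(200):
        if sign * ghi > 0:
            break
        hi *= 2.0
        ghi = g(hi)
    return float(optimize.brentq(g, lo, hi, xtol=tol))


def conditional_mle(dist: ConditionalDistribution) -> tuple[float, str]:
    """Conditional MLE of beta_j; median-unbiased estimate at the support
    boundary (with a note saying so)."""
    tmin, tmax = float(dist.support[0]), float(dist.support[-1])
    t = float(dist.observed)
    if t == tmax:
        est = _solve_monotone(dist.tail_ge, 0.5, increasing=True)
        return est, "median-unbiased substituted (statistic at support maximum)"
    if t == tmin:
        est = _solve_monotone(dist.tail_le, 0.5, increasing=False)
        return est, "median-unbiased substituted (statistic at support minimum)"
    est = _solve_monotone(dist.tilted_mean, t, increasing=True)
    return est, ""


def exact_ci(dist: ConditionalDistribution, alpha: float = 0.05) -> tuple[float, float]:
    """Exact tail-inversion interval; open (infinite) bound at a support
    boundary."""
    t = float(dist.observed)
    tmin, tmax = float(dist.support[0]), float(dist.support[-1])
    if t == tmin:
        lo = -np.inf
    else:
        lo = _solve_monotone(dist.tail_ge, alpha / 2.0, increasing=True)
    if t == tmax:
        hi = np.inf
    else:
        hi = _solve_monotone(dist.tail_le, alpha / 2.0, increasing=False)
    return lo, hi


def midp_ci(dist: ConditionalDistribution, alpha: float = 0.05) -> tuple[float, float]:
    """Mid-P interval: tail probability with half weight on the observed
    point mass, strictly inside the exact interval."""
    t = float(dist.observed)
    tmin, tmax = float(dist.support[0]), float(dist.support[-1])

    def up(b):
        return dist.tail_ge(b) - 0.5 * dist.point_mass(b)

    def down(b):
        return dist.tail_le(b) - 0.5 * dist.point_mass(b)

    if t == tmin:
        lo = -np.inf
    else:
        lo = _solve_monotone(up, alpha / 2.0, increasing=True)
    if t == tmax:
        hi = np.inf
    else:
        hi = _solve_monotone(down, alpha / 2.0, increasing=False)
    return lo, hi


def fit_exact(
    data: BinaryDataset,
    j: int = 1,
    alpha: float = 0.05,
    midp: bool = False,
    state_cap: int = STATE_CAP,
) -> FitResult:
    """Exact (or mid-P) conditional inference for one coefficient,
    packaged as a FitResult with NaN placeholders elsewhere."""
    p = data.n_coef
    est = np.full(p, np.nan)
    lo = np.full(p, np.nan)
    hi = np.full(p, np.nan)
    method = "MDP" if midp else "EX"
    try:
        dist = conditional_distribution(data, j, state_cap=state_cap)
    except DegenerateSupportError as exc:
        return FitResult(method, est, lo, hi, float("nan"), False, 0,
                         notes=str(exc), term_names=data.term_names())
    beta, note = conditional_mle(dist)
    est[j] = beta
    lo[j], hi[j] = midp_ci(dist, alpha) if midp else exact_ci(dist, alpha)
    ll = float(beta * dist.observed + _cond_norm(dist, beta))
    return FitResult(method, est, lo, hi, ll, True, 0,
                     notes=note, term_names=data.term_names())


def _cond_norm(dist: ConditionalDistribution, beta: float) -> float:
    idx = int(np.nonzero(dist.support == dist.observed)[0][0])
    return float(dist.log_probs(beta)[idx] - beta * dist.observed - dist.log_counts[idx]) + float(dist.log_counts[idx])
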