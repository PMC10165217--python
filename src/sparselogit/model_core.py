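"""Binary-logistic likelihood machinery shared by every estimator.

The model is log{pi/(1-pi)} = beta' x with an implicit intercept at
position 0.  Everything here works on per-record weights, so a 2x2
table, a grouped data set and its fully expanded record form give
identical likelihoods, fits and intervals.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "BinaryDataset",
    "FitResult",
    "TwoByTwoTable",
    "log_likelihood",
    "score_and_information",
    "fit_ml",
    "profile_likelihood_ci",
    "wald_ci",
    "read_csv_dataset",
    "write_fit_results",
]

# Fitting constants used by every Newton-type estimator in the package.
SCORE_TOL = 1e-8          # sup-norm of the (modified) score at convergence
MAX_ITER = 50             # Newton iteration cap
OR_GUARD = math.log(999.0)  # estimability window: |log OR| beyond this is "out of range"
PROFILE_TOL = 1e-6        # coefficient-scale tolerance for profile CI endpoints


class InputError(ValueError):
    """Invalid user input (dimension mismatch, bad counts, bad column)."""


@dataclass
class BinaryDataset:
    """A binary outcome, a covariate matrix and per-record weights.

    The covariate matrix does *not* contain the intercept column; it is
    added implicitly at position 0 of the coefficient vector.  Weights
    default to 1 and may be fractional (pseudo-records for data
    augmentation use weight m/2).
    """

    outcome: np.ndarray
    covariates: np.ndarray
    weights: np.ndarray | None = None
    covariate_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        n = self.outcome.shape[0]
        if self.covariates.shape[0] != n:
            raise InputError(
                f"outcome has {n} records but covariates have {self.covariates.shape[0]}"
            )
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != n:
            raise InputError("weights length does not match record count")
        if not np.all(np.isfinite(self.outcome)) or not np.all(np.isfinite(self.covariates)):
            raise InputError("non-finite entries in outcome or covariates")
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise InputError("weights must be finite and nonnegative")
        if not np.all((self.outcome == 0) | (self.outcome == 1)):
            raise InputError("outcome values must be 0 or 1")
        if self.covariate_names is None:
            self.covariate_names = [f"x{j + 1}" for j in range(self.covariates.shape[1])]
        self.covariate_names = list(self.covariate_names)
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise InputError("covariate_names length does not match covariate count")

    @property
    def n_records(self) -> int:
        return self.outcome.shape[0]

    @property
    def n_coef(self) -> int:
        """Number of model coefficients including the intercept."""
        return self.covariates.shape[1] + 1

    def design_matrix(self) -> np.ndarray:
        """Full design matrix with the intercept column prepended."""
        return np.column_stack([np.ones(self.n_records), self.covariates])

    def to_dataframe(self):
        """Export as a pandas DataFrame (outcome, covariates, weight),
        e.g. for writing replicates to CSV for external cross-checks."""
        import pandas as pd

        df = pd.DataFrame(self.covariates, columns=self.covariate_names)
        df.insert(0, "outcome", self.outcome)
        df["weight"] = self.weights
        return df

    def collapse(self) -> "BinaryDataset":
        """Merge identical (outcome, covariate-row) records by summing
        weights.  Fits, likelihoods and intervals are invariant to this
        (the weights contract); it makes large categorical datasets cheap."""
        key = np.column_stack([self.outcome, self.covariates])
        uniq, inverse = np.unique(key, axis=0, return_inverse=True)
        w = np.zeros(uniq.shape[0])
        np.add.at(w, inverse, self.weights)
        return BinaryDataset(uniq[:, 0], uniq[:, 1:], w, self.covariate_names)

    def term_names(self) -> list[str]:
        return ["intercept"] + list(self.covariate_names)


@dataclass
class FitResult:
    """Point and interval estimates from one estimation method."""

    method: str
    estimate: np.ndarray
    interval_low: np.ndarray
    interval_high: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    notes: str = ""
    se: np.ndarray | None = None
    term_names: Sequence[str] | None = None

    def odds_ratio(self, j: int = 1) -> float:
        return float(np.exp(self.estimate[j]))

    def to_records(self) -> list[dict]:
        names = list(self.term_names) if self.term_names is not None else [
            f"b{j}" for j in range(len(self.estimate))
        ]
        out = []
        for j, name in enumerate(names):
            out.append(
                {
                    "method": self.method,
                    "term": name,
                    "estimate": float(self.estimate[j]),
                    "OR": float(np.exp(self.estimate[j])),
                    "ci_low": float(self.interval_low[j]),
                    "ci_high": float(self.interval_high[j]),
                    "converged": bool(self.converged),
                }
            )
        return out


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts (a, b, c, d) = (exposed events, exposed non-events,
    unexposed events, unexposed non-events)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise InputError("2x2 cells must be nonnegative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise InputError("empty 2x2 table")

    def to_dataset(self, exposure_name: str = "exposure") -> BinaryDataset:
        y = np.array([1.0, 0.0, 1.0, 0.0])
        x = np.array([[1.0], [1.0], [0.0], [0.0]])
        w = np.array([self.a, self.b, self.c, self.d], dtype=float)
        keep = w > 0
        return BinaryDataset(y[keep], x[keep], w[keep], [exposure_name])

    def log_cross_ratio(self) -> float:
        return math.log(self.a * self.d / (self.b * self.c))


# ---------------------------------------------------------------------------
# Likelihood, score, information
# ---------------------------------------------------------------------------

def _eta(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return X @ beta


def _loglik_raw(y: np.ndarray, X: np.ndarray, w: np.ndarray, beta: np.ndarray) -> float:
    # sum w [ y*eta - log(1 + exp(eta)) ], computed without forming pi
    eta = _eta(X, beta)
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def _score_info_raw(
    y: np.ndarray, X: np.ndarray, w: np.ndarray, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    pi = special.expit(_eta(X, beta))
    U = X.T @ (w * (y - pi))
    W = w * pi * (1.0 - pi)
    info = (X * W[:, None]).T @ X
    return U, info


def _check_beta(data: BinaryDataset, beta: np.ndarray) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (data.n_coef,):
        raise InputError(
            f"coefficient vector has length {beta.shape}, expected {data.n_coef}"
        )
    return beta


def log_likelihood(data: BinaryDataset, beta: np.ndarray) -> float:
    """Weighted binomial log-likelihood at ``beta`` (intercept at index 0)."""
    beta = _check_beta(data, beta)
    return _loglik_raw(data.outcome, data.design_matrix(), data.weights, beta)


def score_and_information(
    data: BinaryDataset, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Score vector U(beta) and Fisher information X' W X, W = diag(w pi (1-pi))."""
    beta = _check_beta(data, beta)
    return _score_info_raw(data.outcome, data.design_matrix(), data.weights, beta)


# ---------------------------------------------------------------------------
# Generic Newton maximizer with step-halving
# ---------------------------------------------------------------------------

class Objective:
    """A smooth objective with a positive-definite curvature matrix.

    ``hessian`` returns the matrix used as *minus* the Hessian in the
    Newton step (the Fisher information for plain and penalized
    likelihoods), which keeps every estimator on the same iteration.
    """

    def value(self, beta: np.ndarray) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def gradient(self, beta: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def hessian(self, beta: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class MLObjective(Objective):
    def __init__(self, y: np.ndarray, X: np.ndarray, w: np.ndarray):
        self.y, self.X, self.w = y, X, w

    def value(self, beta):
        return _loglik_raw(self.y, self.X, self.w, beta)

    def gradient(self, beta):
        return _score_info_raw(self.y, self.X, self.w, beta)[0]

    def hessian(self, beta):
        return _score_info_raw(self.y, self.X, self.w, beta)[1]


@dataclass
class NewtonOutcome:
    beta: np.ndarray
    value: float
    converged: bool
    n_iter: int
    note: str = ""


def newton_maximize(
    obj: Objective,
    beta0: np.ndarray,
    free: np.ndarray | None = None,
    tol: float = SCORE_TOL,
    max_iter: int = MAX_ITER,
) -> NewtonOutcome:
    """Newton-Raphson with step-halving; optionally only ``free`` coordinates move."""
    beta = np.array(beta0, dtype=float)
    p = beta.shape[0]
    if free is None:
        free = np.ones(p, dtype=bool)
    value = obj.value(beta)
    note = ""
    prev_value = -np.inf
    for it in range(1, max_iter + 1):
        g = obj.gradient(beta)
        if np.max(np.abs(g[free])) < tol:
            return NewtonOutcome(beta, value, True, it - 1, note)
        H = obj.hessian(beta)[np.ix_(free, free)]
        try:
            step = np.linalg.solve(H, g[free])
        except np.linalg.LinAlgError:
            return NewtonOutcome(beta, value, False, it, "singular information")
        # cap the raw Newton step to keep eta in a sane range
        smax = np.max(np.abs(step))
        if smax > 5.0:
            step *= 5.0 / smax
        cand = beta.copy()
        lam = 1.0
        for _ in range(25):
            cand[free] = beta[free] + lam * step
            v = obj.value(cand)
            if v >= value - 1e-12:
                break
            lam *= 0.5
        else:
            return NewtonOutcome(beta, value, False, it, "step-halving failed")
        prev_value, value = value, v
        beta = cand
    # Iteration cap: diverging estimates with a still-improving objective
    # indicate monotone likelihood (separation).
    g = obj.gradient(beta)
    if np.max(np.abs(g[free])) < tol:
        return NewtonOutcome(beta, value, True, max_iter, note)
    note = "separation" if value > prev_value and np.max(np.abs(beta)) > 5.0 else "max iterations"
    return NewtonOutcome(beta, value, False, max_iter, note)


# ---------------------------------------------------------------------------
# ML fit
# ---------------------------------------------------------------------------

def _wald_se(info: np.ndarray) -> np.ndarray | None:
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None
    d = np.diag(cov)
    if np.any(d <= 0):
        return None
    return np.sqrt(d)


def fit_ml(
    data: BinaryDataset,
    tol: float = SCORE_TOL,
    max_iter: int = MAX_ITER,
    ci: str = "none",
    alpha: float = 0.05,
) -> FitResult:
    """Maximum-likelihood logistic fit by Newton-Raphson with step-halving.

    An all-event or all-nonevent outcome, separation, or a singular
    information matrix yields ``converged=False`` (never an exception);
    a converged fit whose non-intercept estimates leave the OR
    estimability window [1/999, 999] is flagged "out of range" in the
    notes, and the replicate-level convergence filter applies the window
    to the exposure coefficient.  ``ci`` selects "none", "wald" or
    "profile" intervals.
    """
    y, X, w = data.outcome, data.design_matrix(), data.weights
    if data.n_coef > data.n_records:
        raise InputError("more coefficients than records")
    obj = MLObjective(y, X, w)
    out = newton_maximize(obj, np.zeros(data.n_coef), tol=tol, max_iter=max_iter)
    converged, note = out.converged, out.note
    if converged and out.value > -1e-3:
        # the likelihood reached a perfect fit: monotone likelihood
        # (complete separation, or a one-level outcome), no finite MLE
        converged, note = False, "separation"
    elif converged and np.max(np.abs(out.beta[1:]), initial=0.0) > OR_GUARD:
        # estimability window: the estimate exists numerically but lies
        # outside OR in [1/999, 999]; flagged for the convergence filter
        note = "out of range"
    se = _wald_se(obj.hessian(out.beta)) if converged else None
    p = data.n_coef
    fit = FitResult(
        method="ML",
        estimate=out.beta,
        interval_low=np.full(p, np.nan),
        interval_high=np.full(p, np.nan),
        loglik=out.value,
        converged=converged,
        n_iter=out.n_iter,
        notes=note,
        se=se,
        term_names=data.term_names(),
    )
    _attach_intervals(fit, data, obj, ci, alpha)
    return fit


def _attach_intervals(
    fit: FitResult, data: BinaryDataset, obj: Objective, ci: str, alpha: float
) -> None:
    if ci == "none" or not fit.converged:
        return
    for j in range(len(fit.estimate)):
        if ci == "wald":
            fit.interval_low[j], fit.interval_high[j] = wald_ci(fit, j, alpha)
        elif ci == "profile":
            lo, hi = profile_ci_for_objective(obj, fit.estimate, fit.loglik, j, alpha, fit.se)
            fit.interval_low[j], fit.interval_high[j] = lo, hi
        else:
            raise InputError(f"unknown interval type {ci!r}")


# ---------------------------------------------------------------------------
# Interval estimation
# ---------------------------------------------------------------------------

def wald_ci(fit: FitResult, j: int, alpha: float = 0.05) -> tuple[float, float]:
    """beta_j +/- z_{1-alpha/2} SE_j from the inverse information."""
    if not fit.converged:
        raise InputError("Wald interval requires a converged fit")
    if fit.se is None:
        name = fit.term_names[j] if fit.term_names else f"coefficient {j}"
        raise InputError(f"singular information; no standard error for {name}")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(fit.estimate[j] - z * fit.se[j]), float(fit.estimate[j] + z * fit.se[j])


def profile_ci_for_objective(
    obj: Objective,
    beta_hat: np.ndarray,
    value_hat: float,
    j: int,
    alpha: float = 0.05,
    se: np.ndarray | None = None,
    max_abs: float = 40.0,
) -> tuple[float, float]:
    """Invert the (penalized) likelihood-ratio test for coordinate ``j``.

    Returns the endpoints of {b : 2[l*(beta_hat) - max_{beta_j=b} l*] <=
    chi2(1, 1-alpha)}.  An endpoint that never crosses the threshold
    before |b| reaches ``max_abs`` is reported as +/-inf (open bound).
    """
    crit = 0.5 * stats.chi2.ppf(1.0 - alpha, 1)
    target = value_hat - crit
    p = beta_hat.shape[0]
    free = np.ones(p, dtype=bool)
    free[j] = False

    def profile(b: float, start: np.ndarray) -> tuple[float, np.ndarray]:
        beta = start.copy()
        beta[j] = b
        out = newton_maximize(obj, beta, free=free, max_iter=200)
        return out.value, out.beta

    step0 = float(se[j]) if se is not None and np.isfinite(se[j]) else 1.0
    bounds = []
    for sign in (-1.0, 1.0):
        lo_b = float(beta_hat[j])
        lo_v = value_hat
        start = beta_hat.copy()
        step = step0
        found = None
        while abs(lo_b) <= max_abs:
            b = lo_b + sign * step
            v, start = profile(b, start)
            if v < target:
                found = (lo_b, b) if sign > 0 else (b, lo_b)
                break
            lo_b, lo_v = b, v
            step *= 2.0  # geometric widening of the bracket
        if found is None:
            bounds.append(sign * np.inf)
            continue

        memo = {found[0]: None, found[1]: None}
        warm = start.copy()

        def signed(b: float, warm=warm) -> float:
            v, beta_new = profile(b, warm)
            warm[:] = beta_new
            return v - target

        lo, hi = found
        b_root = optimize.brentq(signed, lo, hi, xtol=PROFILE_TOL)
        bounds.append(float(b_root))
    return bounds[0], bounds[1]


def profile_likelihood_ci(
    data: BinaryDataset, fit: FitResult, j: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Profile-likelihood CI for coefficient ``j`` of an ML fit."""
    if not fit.converged:
        raise InputError("profile interval requires a converged fit")
    obj = MLObjective(data.outcome, data.design_matrix(), data.weights)
    return profile_ci_for_objective(obj, fit.estimate, fit.loglik, j, alpha, fit.se)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_csv_dataset(
    path: str,
    outcome: str,
    weight: str | None = None,
) -> BinaryDataset:
    """Read a headered CSV with a 0/1 outcome column; remaining numeric
    columns become covariates, used as given (no recoding)."""
    import pandas as pd

    df = pd.read_csv(path)
    if outcome not in df.columns:
        raise InputError(f"no column named {outcome!r} in {path}")
    y = df[outcome].to_numpy(dtype=float)
    w = None
    cov_cols = [c for c in df.columns if c != outcome]
    if weight is not None:
        if weight not in df.columns:
            raise InputError(f"no weight column named {weight!r} in {path}")
        w = df[weight].to_numpy(dtype=float)
        cov_cols = [c for c in cov_cols if c != weight]
    X = df[cov_cols].to_numpy(dtype=float)
    return BinaryDataset(y, X, w, cov_cols)


def write_fit_results(fits: Sequence[FitResult], path: str) -> None:
    """Write fit results to JSON or CSV depending on the file suffix.

    Infinite interval bounds are serialized as the strings "-inf"/"inf"
    in JSON (open intervals) and as empty cells in CSV.
    """
    records = [rec for f in fits for rec in f.to_records()]
    if path.endswith(".json"):
        def clean(v):
            if isinstance(v, float) and math.isinf(v):
                return "inf" if v > 0 else "-inf"
            return v

        with open(path, "w") as fh:
            json.dump([{k: clean(v) for k, v in r.items()} for r in records], fh, indent=1)
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["method", "term", "estimate", "OR", "ci_low", "ci_high", "converged"]
            )
            writer.writeheader()
            for r in records:
                r = dict(r)
                for k in ("ci_low", "ci_high"):
                    if isinstance(r[k], float) and math.isinf(r[k]):
                        r[k] = ""
                writer.writerow(r)
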