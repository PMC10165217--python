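"""Running the estimator suite over replicate streams and summarizing
bias, average OR, coverage and convergence.

The headline summaries restrict every method to the replicates where
the ML fit succeeded (converged with the exposure OR inside
[0.001, 999]), so that all methods are compared on the same datasets;
unrestricted summaries are also available.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import MCMCConfig, PriorSpec, fit_bayes
from .exact import CapacityError, fit_exact
from .firth import fit_firth
from .logf import LogFPriorSpec, fit_logf
from .model_core import BinaryDataset, FitResult, InputError, TwoByTwoTable, fit_ml
from .scenarios import ScenarioConfig, generate_replicates

__all__ = [
    "ALL_METHODS",
    "BUNDLED_TABLES",
    "convergence_filter",
    "fit_method",
    "run_scenario_cell",
    "summarize",
    "required_replications",
    "run_case_study",
]

logger = logging.getLogger("sparselogit")

ALL_METHODS = ("ML", "FIR", "EX", "MDP", "NP", "HG", "F1", "F2")

# printed small-study tables bundled with the package:
#   table1     -- vascular disease vs thromboembolic event case-control counts
#   hydramnios -- hydramnios vs neonatal death cohort counts (1/9 exposed,
#                 16/2,966 unexposed)
BUNDLED_TABLES = {
    "table1": TwoByTwoTable(a=2, b=3, c=12, d=141),
    "hydramnios": TwoByTwoTable(a=1, b=9, c=16, d=2966),
}

OR_WINDOW = (0.001, 999.0)


def convergence_filter(fit: FitResult, j: int = 1) -> bool:
    """True iff the fit converged and the exposure OR lies in [0.001, 999]."""
    if not fit.converged:
        return False
    b = float(fit.estimate[j])
    if not math.isfinite(b):
        return False
    # compared on the log scale so the window boundaries are exact
    return math.log(OR_WINDOW[0]) - 1e-9 <= b <= math.log(OR_WINDOW[1]) + 1e-9


def fit_method(
    data: BinaryDataset,
    method: str,
    ci: str = "none",
    alpha: float = 0.05,
    mcmc: MCMCConfig | None = None,
    exact_j: int = 1,
    state_cap: int | None = None,
) -> FitResult:
    """Dispatch one estimation method by its label."""
    method = method.upper()
    kwargs = {} if state_cap is None else {"state_cap": state_cap}
    if method == "ML":
        return fit_ml(data, ci=ci, alpha=alpha)
    if method == "FIR":
        return fit_firth(data, ci=ci, alpha=alpha)
    if method == "EX":
        return fit_exact(data, j=exact_j, alpha=alpha, midp=False, **kwargs)
    if method == "MDP":
        return fit_exact(data, j=exact_j, alpha=alpha, midp=True, **kwargs)
    if method == "NP":
        return fit_bayes(data, PriorSpec("normal"), mcmc or MCMCConfig())
    if method == "HG":
        return fit_bayes(data, PriorSpec("hyper_g"), mcmc or MCMCConfig())
    if method == "F1":
        return fit_logf(data, LogFPriorSpec(1.0), ci=ci, alpha=alpha)
    if method == "F2":
        return fit_logf(data, LogFPriorSpec(2.0), ci=ci, alpha=alpha)
    raise InputError(f"unknown method {method!r}")


# simulation default: short chains trade Monte-Carlo noise for runtime
SIM_MCMC = MCMCConfig(draws=2000, burnin=500, chains=1)


def _failed_fit(p: int, method: str, note: str) -> FitResult:
    return FitResult(method, np.full(p, np.nan), np.full(p, np.nan),
                     np.full(p, np.nan), float("nan"), False, 0, notes=note)


def run_scenario_cell(
    config: ScenarioConfig,
    methods: Sequence[str] = ("ML", "FIR", "F1", "F2"),
    ci: str = "none",
    mcmc: MCMCConfig | None = None,
    state_cap: int = 200_000,
) -> dict[str, list[FitResult]]:
    """Fit the requested methods on every replicate of one design cell.

    Exact-method fits that exceed the conditional state cap are recorded
    as non-converged with a "state cap" note (and logged once)."""
    results: dict[str, list[FitResult]] = {m.upper(): [] for m in methods}
    capacity_warned = set()
    for rep in generate_replicates(config):
        for m in results:
            cfg = mcmc
            if cfg is None and m in ("NP", "HG"):
                cfg = MCMCConfig(
                    draws=SIM_MCMC.draws,
                    burnin=SIM_MCMC.burnin,
                    chains=SIM_MCMC.chains,
                    seed=config.seed * 1_000_003 + rep.replicate,
                )
            try:
                fit = fit_method(rep.data, m, ci=ci, mcmc=cfg, state_cap=state_cap)
            except CapacityError as exc:
                if m not in capacity_warned:
                    logger.warning("%s skipped in this cell: %s", m, exc)
                    capacity_warned.add(m)
                fit = _failed_fit(rep.data.n_coef, m, "state cap exceeded")
            except InputError as exc:
                # degenerate replicate (e.g. a constant covariate column):
                # recorded as a non-convergence, mirroring the filter's job
                fit = _failed_fit(rep.data.n_coef, m, f"degenerate replicate: {exc}")
            results[m].append(fit)
    return results


def summarize(
    cell_results: dict[str, list[FitResult]],
    true_log_or: float,
    restrict_to_ml_success: bool = True,
    j: int = 1,
) -> pd.DataFrame:
    """Per-method bias, average OR, coverage and convergence rate.

    With the restriction on, every method is averaged over exactly the
    replicates where the ML fit passed the convergence filter.  An
    interval with an open (infinite) bound counts as covering on that
    side.  A cell with zero retained replicates is marked inestimable
    (NaN metrics, n_effective = 0).
    """
    n_reps_set = {len(v) for v in cell_results.values()}
    if len(n_reps_set) != 1:
        raise InputError("methods were run on different numbers of replicates")
    n_reps = n_reps_set.pop()
    if n_reps == 0:
        raise InputError("no replicates to summarize")

    if restrict_to_ml_success:
        if "ML" not in cell_results:
            raise InputError("restriction to ML successes requires ML results")
        keep = np.array([convergence_filter(f, j) for f in cell_results["ML"]])
    else:
        keep = np.ones(n_reps, dtype=bool)

    rows = []
    for method, fits in cell_results.items():
        ok = np.array([convergence_filter(f, j) for f in fits])
        use = keep & ok
        n_eff = int(use.sum())
        if n_eff == 0:
            rows.append(
                dict(method=method, average_or=np.nan, bias_log_or=np.nan,
                     coverage=np.nan, convergence_rate=float(ok.mean()),
                     n_effective=0)
            )
            continue
        est = np.array([float(fits[i].estimate[j]) for i in np.nonzero(use)[0]])
        mean_log = float(est.mean())
        lows = np.array([float(fits[i].interval_low[j]) for i in np.nonzero(use)[0]])
        highs = np.array([float(fits[i].interval_high[j]) for i in np.nonzero(use)[0]])
        with np.errstate(invalid="ignore"):
            covers = (np.isnan(lows) | (lows <= true_log_or)) & (
                np.isnan(highs) | (true_log_or <= highs)
            )
        have_ci = ~(np.isnan(lows) & np.isnan(highs))
        coverage = float(covers[have_ci].mean()) if have_ci.any() else np.nan
        rows.append(
            dict(
                method=method,
                average_or=float(np.exp(mean_log)),
                bias_log_or=mean_log - true_log_or,
                coverage=coverage,
                convergence_rate=float(ok.mean()),
                n_effective=n_eff,
            )
        )
    return pd.DataFrame(rows).set_index("method")


def required_replications(sigma2: float, rho: float = 0.5, ratio: float = 1.1) -> int:
    """Smallest n with z_{0.975} sqrt(2 (1-rho) sigma^2 / n) <= log(ratio).

    This sizes a simulation so the 95% CI for the difference in mean log
    OR between two methods (variance sigma^2 each, correlation rho) is
    within +/- log(ratio).
    """
    if sigma2 <= 0:
        raise InputError("sigma2 must be positive")
    if not 0 <= rho < 1:
        raise InputError("rho must be in [0, 1)")
    if ratio <= 1:
        raise InputError("ratio must exceed 1")
    z = stats.norm.ppf(0.975)
    return int(math.ceil(2.0 * (1.0 - rho) * sigma2 * z * z / math.log(ratio) ** 2))


def run_case_study(
    tables: dict[str, TwoByTwoTable] | None = None,
    methods: Sequence[str] = ALL_METHODS,
    mcmc: MCMCConfig | None = None,
    alpha: float = 0.05,
    data: BinaryDataset | None = None,
    exposure: str | int = 1,
) -> pd.DataFrame:
    """Unadjusted ORs and 95% intervals for each bundled 2x2 table.

    When a full dataset is supplied via ``data`` an adjusted column is
    added from the multivariable model (the exposure named or indexed by
    ``exposure``); the Bayesian rows use the supplied or default chain
    configuration.
    """
    tables = BUNDLED_TABLES if tables is None else tables
    mcmc = mcmc or MCMCConfig(seed=2023)
    rows = []
    for name, tab in tables.items():
        ds = tab.to_dataset()
        for m in methods:
            fit = fit_method(ds, m, ci="profile", alpha=alpha, mcmc=mcmc)
            rows.append(_case_row(name, m, fit, j=1, adjusted=False))
    if data is not None:
        j = exposure if isinstance(exposure, int) else (
            1 + list(data.covariate_names).index(exposure)
        )
        for m in methods:
            fit = fit_method(data, m, ci="profile", alpha=alpha, mcmc=mcmc, exact_j=j)
            rows.append(_case_row("adjusted", m, fit, j=j, adjusted=True))
    return pd.DataFrame(rows)


def _round_or(v: float) -> float:
    """Table style: 1 decimal, 2 significant figures below 10."""
    if not np.isfinite(v):
        return v
    if abs(v) < 10:
        return float(f"{v:.2g}")
    return round(v, 1)


def _case_row(table: str, method: str, fit: FitResult, j: int, adjusted: bool) -> dict:
    or_ = math.exp(float(fit.estimate[j]))
    lo = math.exp(float(fit.interval_low[j]))
    hi = math.exp(float(fit.interval_high[j]))
    return dict(
        table=table,
        method=method,
        adjusted=adjusted,
        OR=or_,
        ci_low=lo,
        ci_high=hi,
        OR_printed=_round_or(or_),
        ci_low_printed=_round_or(lo),
        ci_high_printed=_round_or(hi),
        converged=bool(fit.converged),
        notes=fit.notes,
    )
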