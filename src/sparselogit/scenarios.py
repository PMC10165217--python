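"""Synthetic sparse-data generator: six covariate scenarios.

Each scenario draws categorical covariates, forms the linear predictor
beta0 + beta' x and draws Bernoulli outcomes.  The intercept beta0 is
calibrated so that the *expected* number of events equals a target n_e,
by exact enumeration of the finite covariate support (so the realized
event count is Binomial-distributed around n_e).

Scenarios:

1. x1 ~ Bern(pi_x1), the exposure alone.
2. adds x2 ~ Bern(0.5), independent of x1.
3. correlated pair: x2 ~ Bern(0.5), then x1 | x2 ~ Bern((x2+1)/2 * pi_x1).
4. scenario-3 pair plus x3 ~ Bern(0.3), x4 ~ Bern(0.1).
5. scenario-3 pair plus x3..x7 ~ Bern(0.3, 0.1, 0.5, 0.3, 0.1) and
   x8 ~ Multi(0.8, 0.1, 0.1) coded 0/1/2.
6. a fixed eight-covariate design mimicking an obstetric cohort, with a
   fixed coefficient vector (beta0 = -6.40) instead of calibration.

The exposure effect is true_or_x1 in {1, 4, 16}; every other covariate
gets an odds ratio of 2 in scenarios 2-5.  Multi-level covariates are
coded 0, 1, 2(, 3) and entered as single quantitative columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterator

import numpy as np

from .model_core import BinaryDataset, InputError

__all__ = [
    "ScenarioConfig",
    "ReplicateDataset",
    "scenario_covariate_count",
    "covariate_support",
    "scenario_beta",
    "calibrate_intercept",
    "draw_covariates",
    "generate_replicates",
]

# scenario 6 fixed coefficients (beta2..beta8) and intercept
_SCENARIO6_BETA0 = -6.40
_SCENARIO6_OTHERS = (0.57, 0.96, 2.09, 1.24, 1.52, 0.99, -0.64)
_SCENARIO6_DISTS = (
    ("bern", (0.0033,)),
    ("bern", (0.1858,)),
    ("bern", (0.0100,)),
    ("bern", (0.0157,)),
    ("bern", (0.0391,)),
    ("multi", (0.8021, 0.1715, 0.0264)),
    ("multi", (0.9850, 0.0090, 0.0060)),
    ("multi", (0.8269, 0.0234, 0.0498, 0.0999)),
)

_N_COV = {1: 1, 2: 2, 3: 2, 4: 4, 5: 8, 6: 8}


@dataclass
class ScenarioConfig:
    """One cell of the simulation design."""

    scenario: int
    n: int = 100
    n_e: float = 5.0
    pi_x1: float = 0.05
    true_or_x1: float = 1.0
    other_or: float = 2.0
    seed: int = 0
    n_reps: int = 1000

    def __post_init__(self) -> None:
        if self.scenario not in _N_COV:
            raise InputError(f"unknown scenario {self.scenario}")
        if not 0 < self.pi_x1 < 1:
            raise InputError("pi_x1 must be in (0, 1)")
        if not 0 < self.n_e < self.n:
            raise InputError("expected events must satisfy 0 < n_e < n")
        if self.true_or_x1 <= 0 or self.other_or <= 0:
            raise InputError("odds ratios must be positive")

    @property
    def n_covariates(self) -> int:
        return _N_COV[self.scenario]

    @classmethod
    def from_file(cls, path: str) -> "ScenarioConfig":
        """Load a design cell from a YAML or JSON file."""
        import json

        import yaml

        with open(path) as fh:
            cfg = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
        return cls(**cfg)


@dataclass
class ReplicateDataset:
    """One simulated dataset plus bookkeeping."""

    data: BinaryDataset
    replicate: int
    n_events: int


def scenario_covariate_count(scenario: int) -> int:
    if scenario not in _N_COV:
        raise InputError(f"unknown scenario {scenario}")
    return _N_COV[scenario]


# ---------------------------------------------------------------------------
# Exact joint support of the covariate vector
# ---------------------------------------------------------------------------

def _marginals(config: ScenarioConfig) -> list[tuple[str, tuple[float, ...]]]:
    """Independent marginals for the non-(x1,x2) covariates, by scenario."""
    s = config.scenario
    if s == 4:
        return [("bern", (0.3,)), ("bern", (0.1,))]
    if s == 5:
        return [
            ("bern", (0.3,)),
            ("bern", (0.1,)),
            ("bern", (0.5,)),
            ("bern", (0.3,)),
            ("bern", (0.1,)),
            ("multi", (0.8, 0.1, 0.1)),
        ]
    return []


def _dist_support(kind: str, probs: tuple[float, ...]) -> list[tuple[int, float]]:
    if kind == "bern":
        p = probs[0]
        return [(0, 1.0 - p), (1, p)]
    return [(lvl, pr) for lvl, pr in enumerate(probs)]


def covariate_support(config: ScenarioConfig) -> list[tuple[np.ndarray, float]]:
    """All covariate value combinations with their exact probabilities,
    honoring the scenario-3 dependence of x1 on x2."""
    s = config.scenario
    if s == 1:
        return [
            (np.array([0.0]), 1.0 - config.pi_x1),
            (np.array([1.0]), config.pi_x1),
        ]
    if s == 2:
        out = []
        for x1, p1 in _dist_support("bern", (config.pi_x1,)):
            for x2, p2 in _dist_support("bern", (0.5,)):
                out.append((np.array([x1, x2], dtype=float), p1 * p2))
        return out
    if s in (3, 4, 5):
        out = []
        rest = _marginals(config)
        rest_supports = [_dist_support(k, pr) for k, pr in rest]
        for x2, p2 in _dist_support("bern", (0.5,)):
            p1_cond = (x2 + 1.0) / 2.0 * config.pi_x1
            for x1, p1 in _dist_support("bern", (p1_cond,)):
                base = [x1, x2]
                for combo in product(*rest_supports) if rest_supports else [()]:
                    vals = base + [c[0] for c in combo]
                    pr = p1 * p2
                    for c in combo:
                        pr *= c[1]
                    out.append((np.array(vals, dtype=float), pr))
        return out
    # scenario 6: all independent
    supports = [_dist_support(k, pr) for k, pr in _SCENARIO6_DISTS]
    out = []
    for combo in product(*supports):
        vals = np.array([c[0] for c in combo], dtype=float)
        pr = math.prod(c[1] for c in combo)
        out.append((vals, pr))
    return out


def scenario_beta(config: ScenarioConfig) -> np.ndarray:
    """Full coefficient vector (intercept first) for the scenario cell."""
    k = config.n_covariates
    beta = np.empty(k + 1)
    beta[1] = math.log(config.true_or_x1)
    if config.scenario == 6:
        beta[0] = _SCENARIO6_BETA0
        beta[2:] = _SCENARIO6_OTHERS
    else:
        beta[2:] = math.log(config.other_or)
        beta[0] = calibrate_intercept(config)
    return beta


def calibrate_intercept(config: ScenarioConfig) -> float:
    """beta0 solving E[expit(beta0 + beta' x)] = n_e / n exactly over the
    covariate support, by bisection to 1e-10."""
    if config.scenario == 6:
        raise InputError("scenario 6 uses the fixed intercept -6.40")
    target = config.n_e / config.n
    support = covariate_support(config)
    xs = np.array([x for x, _ in support])
    ps = np.array([p for _, p in support])
    slopes = np.empty(config.n_covariates)
    slopes[0] = math.log(config.true_or_x1)
    slopes[1:] = math.log(config.other_or)
    eta_x = xs @ slopes

    from scipy.special import expit

    def event_prob(b0: float) -> float:
        return float(np.sum(ps * expit(b0 + eta_x)))

    lo, hi = -50.0, 50.0
    for _ in range(300):
        mid = 0.5 * (lo + hi)
        if event_prob(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Random draws
# ---------------------------------------------------------------------------

def _draw_multi(rng: np.random.Generator, probs: tuple[float, ...], n: int) -> np.ndarray:
    return rng.choice(len(probs), size=n, p=np.asarray(probs) / sum(probs)).astype(float)


def draw_covariates(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """One n x k covariate matrix for the scenario."""
    n, s = config.n, config.scenario
    if s == 1:
        return (rng.uniform(size=(n, 1)) < config.pi_x1).astype(float)
    if s == 2:
        x1 = (rng.uniform(size=n) < config.pi_x1).astype(float)
        x2 = (rng.uniform(size=n) < 0.5).astype(float)
        return np.column_stack([x1, x2])
    if s in (3, 4, 5):
        x2 = (rng.uniform(size=n) < 0.5).astype(float)
        p1 = (x2 + 1.0) / 2.0 * config.pi_x1
        x1 = (rng.uniform(size=n) < p1).astype(float)
        cols = [x1, x2]
        for kind, probs in _marginals(config):
            if kind == "bern":
                cols.append((rng.uniform(size=n) < probs[0]).astype(float))
            else:
                cols.append(_draw_multi(rng, probs, n))
        return np.column_stack(cols)
    # scenario 6
    cols = []
    for kind, probs in _SCENARIO6_DISTS:
        if kind == "bern":
            cols.append((rng.uniform(size=n) < probs[0]).astype(float))
        else:
            cols.append(_draw_multi(rng, probs, n))
    return np.column_stack(cols)


def generate_replicates(config: ScenarioConfig) -> Iterator[ReplicateDataset]:
    """Seeded stream of ``n_reps`` replicate datasets.

    One master seed spawns a substream per replicate, so replicate r is
    reproducible in isolation.  Degenerate replicates (zero events,
    constant covariate columns) are passed through unchanged; handling
    them is the estimators' job.
    """
    from scipy.special import expit

    beta = scenario_beta(config)
    names = [f"x{j + 1}" for j in range(config.n_covariates)]
    master = np.random.SeedSequence(config.seed)
    for r, ss in enumerate(master.spawn(config.n_reps)):
        rng = np.random.default_rng(ss)
        X = draw_covariates(config, rng)
        pi = expit(beta[0] + X @ beta[1:])
        y = (rng.uniform(size=config.n) < pi).astype(float)
        data = BinaryDataset(y, X, None, names)
        yield ReplicateDataset(data=data, replicate=r, n_events=int(y.sum()))
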