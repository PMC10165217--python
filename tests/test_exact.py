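"""Exact conditional logistic inference."""

import itertools
import math

import numpy as np
import pytest

from sparselogit import (
    BinaryDataset,
    DegenerateSupportError,
    InputError,
    TwoByTwoTable,
    conditional_distribution,
    conditional_mle,
    exact_ci,
    fit_exact,
    fit_ml,
    midp_ci,
)
from sparselogit.exact import CapacityError


def brute_force_counts(data: BinaryDataset, j: int) -> dict[int, int]:
    """Exhaustive 2^n enumeration oracle over expanded records."""
    y = np.repeat(data.outcome, data.weights.astype(int))
    X = np.repeat(data.design_matrix(), data.weights.astype(int), axis=0)
    n, p = X.shape
    t_all = y @ X
    counts: dict[int, int] = {}
    for bits in itertools.product([0, 1], repeat=n):
        ys = np.asarray(bits, dtype=float)
        t = ys @ X
        if all(t[c] == t_all[c] for c in range(p) if c != j):
            counts[int(round(t[j]))] = counts.get(int(round(t[j])), 0) + 1
    return counts


class TestConditionalDistribution:
    def test_2x2_matches_hypergeometric_formula(self, hydramnios):
        dist = conditional_distribution(hydramnios.to_dataset(), 1)
        n1, n0, m = 10, 2982, 17
        assert list(dist.support.astype(int)) == list(range(0, 11))
        for t, c in zip(dist.support.astype(int), dist.counts):
            assert c == math.comb(n1, t) * math.comb(n0, m - t)

    def test_probabilities_normalize(self, hydramnios):
        dist = conditional_distribution(hydramnios.to_dataset(), 1)
        for beta in (-1.0, 0.0, 2.5):
            assert dist.probs(beta).sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("trial", range(8))
    def test_counts_equal_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(6, 12))
        k = int(rng.integers(1, 4))
        X = rng.integers(0, 3, size=(n, k)).astype(float)
        y = rng.integers(0, 2, size=n).astype(float)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        data = BinaryDataset(y, X)
        oracle = brute_force_counts(data, 1)
        try:
            dist = conditional_distribution(data, 1)
        except DegenerateSupportError:
            assert len(oracle) == 1
            return
        got = dict(zip(dist.support.astype(int), dist.counts))
        assert got == oracle

    def test_grouped_weights_equal_expanded_records(self, rng):
        y = np.array([1.0, 0.0, 1.0, 0.0])
        X = np.array([[1.0], [1.0], [0.0], [0.0]])
        w = np.array([2.0, 3.0, 4.0, 5.0])
        grouped = conditional_distribution(BinaryDataset(y, X, w), 1)
        expanded = conditional_distribution(
            BinaryDataset(np.repeat(y, w.astype(int)), np.repeat(X, w.astype(int), axis=0)), 1
        )
        assert list(grouped.support) == list(expanded.support)
        assert grouped.counts == expanded.counts

    def test_non_integer_covariates_rejected(self):
        data = BinaryDataset(np.array([1.0, 0.0]), np.array([[0.5], [1.0]]))
        with pytest.raises(InputError):
            conditional_distribution(data, 1)

    def test_state_cap_enforced(self, hydramnios):
        with pytest.raises(CapacityError):
            conditional_distribution(hydramnios.to_dataset(), 1, state_cap=3)

    def test_tilted_mean_monotone_in_beta(self, hydramnios):
        dist = conditional_distribution(hydramnios.to_dataset(), 1)
        grid = np.linspace(-3, 3, 25)
        means = [dist.tilted_mean(b) for b in grid]
        assert np.all(np.diff(means) > 0)


class TestConditionalMLE:
    def test_hydramnios_or(self, hydramnios):
        dist = conditional_distribution(hydramnios.to_dataset(), 1)
        beta, note = conditional_mle(dist)
        assert note == ""
        assert math.exp(beta) == pytest.approx(20.5, abs=0.05)

    def test_symmetric_distribution_gives_zero(self):
        dist = conditional_distribution(TwoByTwoTable(2, 2, 2, 2).to_dataset(), 1)
        beta, _ = conditional_mle(dist)
        assert beta == pytest.approx(0.0, abs=1e-9)

    def test_matches_golden_section_maximizer(self, hydramnios):
        from scipy.optimize import minimize_scalar

        dist = conditional_distribution(hydramnios.to_dataset(), 1)
        beta, _ = conditional_mle(dist)

        def negcondll(b):
            lp = dist.log_probs(b)
            idx = int(np.nonzero(dist.support == dist.observed)[0][0])
            return -lp[idx]

        res = minimize_scalar(negcondll, bracket=(0, 3, 6), method="golden",
                              options={"xtol": 1e-10})
        assert beta == pytest.approx(res.x, abs=1e-6)

    def test_median_unbiased_at_support_boundary(self):
        # all events exposed: observed statistic at the support maximum
        dist = conditional_distribution(TwoByTwoTable(3, 4, 0, 9).to_dataset(), 1)
        beta, note = conditional_mle(dist)
        assert "median-unbiased" in note
        assert dist.tail_ge(beta) == pytest.approx(0.5, abs=1e-8)

    def test_2x2_conditional_within_10pct_below_unconditional(self, hydramnios, vascular):
        for table in (hydramnios, vascular):
            data = table.to_dataset()
            ml = fit_ml(data).estimate[1]
            cond, _ = conditional_mle(conditional_distribution(data, 1))
            assert abs(cond) <= abs(ml) + 1e-12
            assert cond == pytest.approx(ml, rel=0.10)


class TestIntervals:
    def test_hydramnios_exact_interval(self, hydramnios):
        dist = conditional_distribution(hydramnios.to_dataset(), 1)
        lo, hi = exact_ci(dist)
        assert math.exp(lo) == pytest.approx(0.4, abs=0.05)
        assert math.exp(hi) == pytest.approx(164.2, abs=0.05)

    def test_hydramnios_midp_interval(self, hydramnios):
        dist = conditional_distribution(hydramnios.to_dataset(), 1)
        lo, hi = midp_ci(dist)
        assert math.exp(lo) == pytest.approx(0.9, abs=0.05)
        assert math.exp(hi) == pytest.approx(136.1, abs=0.05)

    def test_defining_tail_equations_hold(self, hydramnios):
        dist = conditional_distribution(hydramnios.to_dataset(), 1)
        lo, hi = exact_ci(dist, alpha=0.05)
        assert dist.tail_ge(lo) == pytest.approx(0.025, abs=1e-6)
        assert dist.tail_le(hi) == pytest.approx(0.025, abs=1e-6)
        mlo, mhi = midp_ci(dist, alpha=0.05)
        assert dist.tail_ge(mlo) - 0.5 * dist.point_mass(mlo) == pytest.approx(0.025, abs=1e-6)
        assert dist.tail_le(mhi) - 0.5 * dist.point_mass(mhi) == pytest.approx(0.025, abs=1e-6)

    def test_midp_strictly_inside_exact(self, hydramnios, vascular):
        for table in (hydramnios, vascular):
            dist = conditional_distribution(table.to_dataset(), 1)
            elo, ehi = exact_ci(dist)
            mlo, mhi = midp_ci(dist)
            assert elo < mlo and mhi < ehi

    def test_open_bound_at_boundary(self):
        dist = conditional_distribution(TwoByTwoTable(3, 4, 0, 9).to_dataset(), 1)
        lo, hi = exact_ci(dist)
        assert hi == np.inf
        assert np.isfinite(lo)


class TestFitExact:
    def test_point_estimate_same_for_exact_and_midp(self, hydramnios):
        data = hydramnios.to_dataset()
        ex = fit_exact(data, midp=False)
        mdp = fit_exact(data, midp=True)
        assert ex.estimate[1] == pytest.approx(mdp.estimate[1], abs=1e-12)
        assert ex.method == "EX" and mdp.method == "MDP"

    def test_degenerate_support_reported_inestimable(self):
        # the conditioning margins force a unique outcome vector
        y = np.array([1.0, 0.0])
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        fit = fit_exact(BinaryDataset(y, X), j=1)
        assert not fit.converged
        assert "inestimable" in fit.notes
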