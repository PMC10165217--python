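"""Likelihood machinery, ML fitting and interval estimation."""

import math

import numpy as np
import pytest
from scipy import stats

from sparselogit import (
    BinaryDataset,
    InputError,
    TwoByTwoTable,
    fit_ml,
    log_likelihood,
    profile_likelihood_ci,
    read_csv_dataset,
    score_and_information,
    wald_ci,
    write_fit_results,
)
from conftest import random_dataset


def naive_loglik(data, beta):
    """Independent per-record loop oracle."""
    total = 0.0
    for i in range(data.n_records):
        eta = beta[0] + float(data.covariates[i] @ beta[1:])
        pi = 1.0 / (1.0 + math.exp(-eta))
        total += data.weights[i] * (
            data.outcome[i] * math.log(pi) + (1 - data.outcome[i]) * math.log(1 - pi)
        )
    return total


class TestLogLikelihood:
    def test_zero_beta_gives_minus_n_log2(self, rng):
        data = random_dataset(rng, n=17)
        assert log_likelihood(data, np.zeros(3)) == pytest.approx(-17 * math.log(2))

    def test_matches_naive_loop(self, rng):
        for _ in range(5):
            data = random_dataset(rng, n=12, k=2, weights=True)
            beta = rng.normal(size=3)
            assert log_likelihood(data, beta) == pytest.approx(
                naive_loglik(data, beta), rel=1e-12
            )

    def test_weight_doubling_equals_record_duplication(self, rng):
        data = random_dataset(rng, n=10, k=1)
        doubled = BinaryDataset(
            data.outcome, data.covariates, 2.0 * data.weights, data.covariate_names
        )
        stacked = BinaryDataset(
            np.concatenate([data.outcome] * 2),
            np.vstack([data.covariates] * 2),
            None,
            data.covariate_names,
        )
        beta = rng.normal(size=2)
        assert log_likelihood(doubled, beta) == pytest.approx(
            log_likelihood(stacked, beta), rel=1e-12
        )

    def test_dimension_mismatch_raises(self, rng):
        data = random_dataset(rng)
        with pytest.raises(InputError):
            log_likelihood(data, np.zeros(5))


class TestScoreAndInformation:
    def test_score_vanishes_at_optimum(self, rng):
        data = random_dataset(rng, n=40)
        fit = fit_ml(data)
        assert fit.converged
        U, _ = score_and_information(data, fit.estimate)
        assert np.max(np.abs(U)) < 1e-8

    def test_finite_difference_gradient(self, rng):
        data = random_dataset(rng, n=15, weights=True)
        beta = rng.normal(scale=0.5, size=3)
        U, _ = score_and_information(data, beta)
        eps = 1e-6
        for j in range(3):
            bp, bm = beta.copy(), beta.copy()
            bp[j] += eps
            bm[j] -= eps
            fd = (log_likelihood(data, bp) - log_likelihood(data, bm)) / (2 * eps)
            assert fd == pytest.approx(U[j], rel=1e-5, abs=1e-6)

    def test_intercept_only_information_closed_form(self):
        # covariate column held at 0, so only the intercept is informative
        n = 25
        data = BinaryDataset(np.r_[np.ones(10), np.zeros(15)], np.zeros((n, 1)))
        beta = np.array([0.7, 0.0])
        _, info = score_and_information(data, beta)
        expected = n * math.exp(0.7) / (1 + math.exp(0.7)) ** 2
        assert info[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_information_positive_semidefinite(self, rng):
        data = random_dataset(rng, weights=True)
        _, info = score_and_information(data, rng.normal(size=3))
        assert np.all(np.linalg.eigvalsh(info) >= -1e-10)


class TestFitML:
    def test_vascular_table_or(self, vascular):
        fit = fit_ml(vascular.to_dataset())
        assert fit.odds_ratio() == pytest.approx(7.83, abs=0.005)

    def test_balanced_table_or_is_one(self):
        fit = fit_ml(TwoByTwoTable(10, 10, 10, 10).to_dataset())
        assert fit.odds_ratio() == pytest.approx(1.0, abs=1e-9)

    def test_hydramnios_or(self, hydramnios):
        fit = fit_ml(hydramnios.to_dataset())
        assert fit.odds_ratio() == pytest.approx(20.6, abs=0.05)

    @pytest.mark.parametrize("cells", [(2, 3, 12, 141), (1, 9, 16, 2966), (5, 7, 3, 11)])
    def test_saturated_2x2_equals_log_cross_ratio(self, cells):
        table = TwoByTwoTable(*cells)
        fit = fit_ml(table.to_dataset())
        assert fit.estimate[1] == pytest.approx(table.log_cross_ratio(), abs=1e-8)

    def test_all_event_outcome_flagged_not_raised(self):
        data = BinaryDataset(np.ones(8), np.arange(8, dtype=float)[:, None])
        fit = fit_ml(data)
        assert not fit.converged

    def test_separation_flagged(self):
        # exposure perfectly predicts the outcome
        x = np.r_[np.ones(5), np.zeros(5)][:, None]
        y = np.r_[np.ones(5), np.zeros(5)]
        fit = fit_ml(BinaryDataset(y, x))
        assert not fit.converged


class TestWaldCI:
    def test_closed_form_2x2_halfwidth(self, vascular):
        fit = fit_ml(vascular.to_dataset())
        lo, hi = wald_ci(fit, 1)
        half = stats.norm.ppf(0.975) * math.sqrt(1 / 2 + 1 / 3 + 1 / 12 + 1 / 141)
        assert hi - lo == pytest.approx(2 * half, rel=1e-9)

    def test_label_swap_negates_endpoints(self, vascular):
        fit = fit_ml(vascular.to_dataset())
        swapped = TwoByTwoTable(vascular.b, vascular.a, vascular.d, vascular.c)
        fit2 = fit_ml(swapped.to_dataset())
        lo, hi = wald_ci(fit, 1)
        lo2, hi2 = wald_ci(fit2, 1)
        assert (lo2, hi2) == pytest.approx((-hi, -lo), rel=1e-9)


class TestProfileCI:
    def test_hydramnios_interval(self, hydramnios):
        data = hydramnios.to_dataset()
        fit = fit_ml(data)
        lo, hi = profile_likelihood_ci(data, fit, 1)
        assert math.exp(lo) == pytest.approx(1.1, abs=0.05)
        assert math.exp(hi) == pytest.approx(119.6, abs=0.05)

    def test_contains_estimate_and_deviance_at_endpoints(self, rng):
        data = random_dataset(rng, n=60)
        fit = fit_ml(data)
        lo, hi = profile_likelihood_ci(data, fit, 1)
        assert lo < fit.estimate[1] < hi
        crit = stats.chi2.ppf(0.95, 1)
        for endpoint in (lo, hi):
            profile = _grid_profile(data, 1, endpoint)
            dev = 2 * (fit.loglik - profile)
            assert dev == pytest.approx(crit, abs=1e-3)

    def test_agrees_with_wald_on_large_balanced_data(self, rng):
        n = 4000
        x = (rng.uniform(size=n) < 0.5).astype(float)[:, None]
        eta = -0.2 + 0.5 * x[:, 0]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
        data = BinaryDataset(y, x)
        fit = fit_ml(data)
        plo, phi = profile_likelihood_ci(data, fit, 1)
        wlo, whi = wald_ci(fit, 1)
        assert plo == pytest.approx(wlo, rel=0.02, abs=0.02)
        assert phi == pytest.approx(whi, rel=0.02, abs=0.02)

    def test_nonconverged_fit_rejected(self):
        x = np.r_[np.ones(5), np.zeros(5)][:, None]
        y = np.r_[np.ones(5), np.zeros(5)]
        data = BinaryDataset(y, x)
        fit = fit_ml(data)
        with pytest.raises(InputError):
            profile_likelihood_ci(data, fit, 1)


def _grid_profile(data, j, value):
    """Deviance-inversion oracle: maximize over the other coefficients by
    dense Newton-free grid refinement around the ML solution."""
    from scipy.optimize import minimize

    def nll(rest):
        beta = np.empty(data.n_coef)
        beta[j] = value
        beta[[i for i in range(data.n_coef) if i != j]] = rest
        return -log_likelihood(data, beta)

    res = minimize(nll, np.zeros(data.n_coef - 1), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    return -res.fun


class TestIO:
    def test_csv_round_trip(self, tmp_path, rng):
        import pandas as pd

        df = pd.DataFrame(
            {
                "y": [0, 1, 0, 1, 1, 0],
                "exposure": [0, 1, 1, 0, 1, 0],
                "age_group": [1, 2, 0, 1, 2, 0],
            }
        )
        path = tmp_path / "data.csv"
        df.to_csv(path, index=False)
        data = read_csv_dataset(str(path), outcome="y")
        assert data.covariate_names == ["exposure", "age_group"]
        assert data.n_records == 6
        with pytest.raises(InputError):
            read_csv_dataset(str(path), outcome="missing")

    def test_fit_result_writers(self, tmp_path, vascular):
        import json

        fit = fit_ml(vascular.to_dataset(), ci="wald")
        jpath = tmp_path / "fits.json"
        cpath = tmp_path / "fits.csv"
        write_fit_results([fit], str(jpath))
        write_fit_results([fit], str(cpath))
        records = json.loads(jpath.read_text())
        assert records[1]["method"] == "ML"
        assert records[1]["OR"] == pytest.approx(7.83, abs=0.005)
        assert "method,term" in cpath.read_text().splitlines()[0]
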