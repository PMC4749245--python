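"""Combination learners: BP network training and (mixed) logistic fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import expit

from vfshock import (
    DegenerateTrainingError,
    FEATURE_SETS,
    LogisticModel,
    SchemaError,
    fit_all_combinations,
    fit_logistic,
    predict_score,
    roc_curve,
    train_bp_network,
)
from vfshock.models import _fit_mixed_logit, _group_index, _mixed_loglik
from numpy.polynomial.hermite_e import hermegauss


def _frame(x, y, pid=None):
    d = {"outcome": y}
    x = np.atleast_2d(x.T).T
    for j in range(x.shape[1]):
        d[f"x{j}" if x.shape[1] > 1 else "amsa"] = x[:, j]
    d["patient_id"] = pid if pid is not None else np.arange(len(y))
    return pd.DataFrame(d)


class TestBpNetwork:
    def test_separable_data_near_perfect_ranking(self, rng):
        x = np.r_[rng.normal(-2, 0.5, (100, 2)), rng.normal(2, 0.5, (100, 2))]
        y = np.r_[np.zeros(100), np.ones(100)]
        frame = _frame(x, y)
        net = train_bp_network(frame, ["x0", "x1"], seed=0)
        auc = roc_curve(predict_score(net, frame), y).auc
        assert auc > 0.99

    def test_constant_feature_no_signal(self, rng):
        y = rng.integers(0, 2, 300)
        frame = _frame(np.ones(300), y)
        net = train_bp_network(frame, ["amsa"], seed=1)
        valid = _frame(np.ones(200), rng.integers(0, 2, 200))
        auc = roc_curve(predict_score(net, valid),
                        valid["outcome"]).auc
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_seeded_determinism_and_score_reproduction(self, rng):
        x = rng.normal(size=(120, 2))
        y = (x[:, 0] + rng.normal(size=120) > 0).astype(int)
        frame = _frame(x, y)
        n1 = train_bp_network(frame, ["x0", "x1"], seed=5)
        n2 = train_bp_network(frame, ["x0", "x1"], seed=5)
        np.testing.assert_array_equal(n1.theta, n2.theta)
        np.testing.assert_array_equal(predict_score(n1, frame),
                                      predict_score(n2, frame))

    def test_objective_trace_non_increasing(self, rng):
        x = rng.normal(size=(150, 2))
        y = (x.sum(axis=1) + rng.normal(size=150) > 0).astype(int)
        net = train_bp_network(_frame(x, y), ["x0", "x1"], seed=2)
        for stage in net.training_trace:
            assert np.all(np.diff(stage) <= 1e-8)

    def test_single_class_rejected(self):
        frame = _frame(np.arange(10.0), np.ones(10, int))
        with pytest.raises(DegenerateTrainingError):
            train_bp_network(frame, ["amsa"], seed=0)

    def test_scores_strictly_inside_unit_interval(self, rng):
        x = np.r_[np.full(50, -100.0), np.full(50, 100.0)]
        y = np.r_[np.zeros(50), np.ones(50)]
        frame = _frame(x, y)
        net = train_bp_network(frame, ["amsa"], seed=0)
        s = predict_score(net, frame)
        assert np.all((s > 0) & (s < 1))


class TestLogistic:
    def test_null_model_scores_half(self):
        model = LogisticModel(covariates=["amsa"], coef=np.zeros(1),
                              intercept=0.0, random_intercept_sd=0.0,
                              cov_params=np.eye(2), log_likelihood=0.0,
                              converged=True, n_obs=0, n_groups=0)
        frame = _frame(np.linspace(0, 30, 7), np.zeros(7, int))
        assert np.allclose(predict_score(model, frame), 0.5)

    def test_monotone_scores_in_amsa(self, default_frame):
        sub = default_frame[default_frame["shock_index"] > 1]
        model, _ = fit_logistic(sub, ["amsa"], random_intercept=False)
        assert model.coef[0] > 0
        grid = _frame(np.linspace(1, 30, 20), np.zeros(20, int))
        assert np.all(np.diff(predict_score(model, grid)) > 0)

    def test_missing_covariate_schema_error(self, default_frame):
        model, _ = fit_logistic(default_frame, ["amsa"],
                                random_intercept=False)
        with pytest.raises(SchemaError):
            predict_score(model, default_frame.drop(columns=["amsa"]))

    def test_ghq_likelihood_matches_quadrature_oracle(self, rng):
        """Adaptive GHQ log-likelihood equals brute-force integration."""
        x = rng.normal(0, 1, 12)[:, None]
        y = rng.integers(0, 2, 12).astype(float)
        g = np.repeat([0, 1, 2], 4)
        params = np.array([0.3, -0.6, np.log(0.8)])
        order, starts = _group_index(g)
        nodes, weights = hermegauss(21)
        got = _mixed_loglik(params, x[order], y[order], starts, nodes, weights)

        sigma = np.exp(params[-1])
        expected = 0.0
        for i in range(3):
            xi, yi = x[g == i, 0], y[g == i]

            def integrand(b, xi=xi, yi=yi):
                p = expit(params[0] + params[1] * xi + b)
                lik = np.prod(p**yi * (1 - p) ** (1 - yi))
                return lik * np.exp(-0.5 * b**2 / sigma**2) / (
                    sigma * np.sqrt(2 * np.pi))

            expected += np.log(quad(integrand, -10, 10)[0])
        assert got == pytest.approx(expected, rel=1e-8)

    def test_sigma_zero_data_collapses_to_pooled(self, rng):
        """Without a true random effect, the RE fit matches the pooled fit."""
        n = 1200
        x = rng.normal(12, 8, n)
        y = (rng.random(n) < expit(-2 + 0.15 * x)).astype(int)
        g = np.repeat(np.arange(n // 4), 4)
        frame = _frame(x, y, pid=g)
        re_model, _ = fit_logistic(frame, ["amsa"], random_intercept=True)
        pooled, _ = fit_logistic(frame, ["amsa"], random_intercept=False)
        assert re_model.random_intercept_sd < 0.15
        assert re_model.coef[0] == pytest.approx(pooled.coef[0], rel=0.05)

    def test_nested_covariate_never_lowers_loglik(self, default_frame):
        sub = default_frame[default_frame["shock_index"] > 1]
        small, _ = fit_logistic(sub, ["amsa"], random_intercept=False)
        big, _ = fit_logistic(sub, ["amsa", "psi"], random_intercept=False)
        assert big.log_likelihood >= small.log_likelihood - 1e-6

    def test_odds_ratio_result_consistency(self, default_frame):
        sub = default_frame[default_frame["shock_index"] > 1]
        model, results = fit_logistic(sub, ["amsa"], random_intercept=True)
        r = results[0]
        assert r.ci_low <= r.odds_ratio <= r.ci_high
        assert r.odds_ratio == pytest.approx(np.exp(model.coef[0]))
        assert 0 <= r.p_value <= 1

    def test_single_class_rejected(self):
        frame = _frame(np.arange(10.0), np.ones(10, int))
        with pytest.raises(DegenerateTrainingError):
            fit_logistic(frame, ["amsa"], random_intercept=False)


class TestFitAllCombinations:
    def test_input_dimensions(self, default_frame):
        sub = default_frame[default_frame["shock_index"] > 1]
        models = fit_all_combinations(sub, method="network", seed=3)
        dims = [models[name].n_inputs for name in ("AMSA", "C1", "C2", "C3")]
        assert dims == [1, 2, 2, 3]

    def test_first_stratum_logistic_reduces_to_amsa(self, default_frame):
        """Constant PSI/dAMSA on first shocks: all fits equal AMSA-only."""
        first = default_frame[default_frame["shock_index"] == 1]
        models = fit_all_combinations(first, method="logistic", seed=0,
                                      random_intercept=False)
        base = predict_score(models["AMSA"], first)
        for name in ("C1", "C2", "C3"):
            np.testing.assert_allclose(predict_score(models[name], first),
                                       base)

    def test_seed_changes_network_not_logistic(self, default_frame):
        sub = default_frame[default_frame["shock_index"] > 1]
        n1 = fit_all_combinations(sub, "network", seed=1)["C3"]
        n2 = fit_all_combinations(sub, "network", seed=2)["C3"]
        assert not np.allclose(n1.theta, n2.theta)
        l1 = fit_all_combinations(sub, "logistic", seed=1,
                                  random_intercept=False)["C3"]
        l2 = fit_all_combinations(sub, "logistic", seed=2,
                                  random_intercept=False)["C3"]
        np.testing.assert_allclose(l1.coef, l2.coef)
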