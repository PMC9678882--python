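"""Nodewise LASSO estimation: solver oracle checks, EBIC, aggregation."""

from __future__ import annotations

from dataclasses import replace
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from morbinet.mgm import (
    EstimationConfig,
    NodewiseFit,
    aggregate_network,
    build_design,
    ebic,
    fit_mgm,
    fit_node_path,
    fit_penalized_node,
    lambda_path,
    select_lambda,
)
from morbinet.solver import fit_l1_logistic, lambda_max, penalized_objective
from morbinet.synthetic import PlantedModel, SimulationConfig, sample_cohort


def lbfgs_l1_objective(X, y, lam):
    """Independent oracle: minimize the penalized objective via L-BFGS-B on
    the smooth split-variable reformulation beta = u - v with u, v >= 0."""
    n, d = X.shape

    def f(z):
        b0, u, v = z[0], z[1 : 1 + d], z[1 + d :]
        beta = u - v
        eta = b0 + X @ beta
        nll = np.sum(np.logaddexp(0.0, eta) - y * eta) / n
        return nll + lam * np.sum(u + v)

    z0 = np.zeros(1 + 2 * d)
    bounds = [(None, None)] + [(0, None)] * (2 * d)
    res = minimize(f, z0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 20000, "ftol": 1e-14, "gtol": 1e-10})
    return res.fun


def _random_instance(rng, n, d):
    X = (rng.random((n, d)) < rng.uniform(0.15, 0.5)).astype(float)
    beta = rng.normal(0, 0.8, d)
    eta = -0.5 + X @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    if y.min() == y.max():  # avoid degenerate responses
        y[0] = 1 - y[0]
    return X, y


class TestSolver:
    def test_lambda_max_matches_hand_computed_gradient(self):
        rng = np.random.default_rng(0)
        X, y = _random_instance(rng, 50, 2)
        expected = np.abs(X.T @ (y - y.mean())).max() / 50
        assert lambda_max(X, y) == pytest.approx(expected, rel=1e-12)

    def test_at_lambda_max_all_coefficients_exactly_zero(self):
        rng = np.random.default_rng(1)
        X, y = _random_instance(rng, 200, 4)
        lmax = lambda_max(X, y)
        for lam in (lmax, 1.5 * lmax):
            _, beta = fit_l1_logistic(X, y, lam)
            assert np.all(beta == 0.0)

    def test_unpenalized_fit_matches_lbfgs_mle(self):
        rng = np.random.default_rng(2)
        X, y = _random_instance(rng, 200, 3)
        b0, beta = fit_l1_logistic(X, y, 0.0)
        obj = penalized_objective(X, y, 0.0, b0, beta)
        assert obj == pytest.approx(lbfgs_l1_objective(X, y, 0.0), abs=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_matches_convex_solver_at_intermediate_lambda(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, d = int(rng.integers(100, 500)), int(rng.integers(2, 7))
        X, y = _random_instance(rng, n, d)
        lam = 0.3 * lambda_max(X, y)
        b0, beta = fit_l1_logistic(X, y, lam)
        mine = penalized_objective(X, y, lam, b0, beta)
        oracle = lbfgs_l1_objective(X, y, lam)
        assert mine <= oracle + 1e-6

    def test_matches_sklearn_saga(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(3)
        X, y = _random_instance(rng, 400, 5)
        lam = 0.2 * lambda_max(X, y)
        b0, beta = fit_l1_logistic(X, y, lam)
        clf = LogisticRegression(
            l1_ratio=1.0, C=1 / (len(y) * lam), solver="saga",
            tol=1e-10, max_iter=100_000,
        )
        clf.fit(X, y)
        mine = penalized_objective(X, y, lam, b0, beta)
        theirs = penalized_objective(X, y, lam, clf.intercept_[0], clf.coef_[0])
        assert mine == pytest.approx(theirs, abs=1e-7)


class TestDesign:
    def test_k2_column_count(self):
        X = np.eye(4)
        design, terms, _ = build_design(np.vstack([X, 1 - X]), 0, 2)
        assert design.shape[1] == 3
        assert terms == [(1,), (2,), (3,)]

    def test_k3_adds_pairwise_products(self):
        rng = np.random.default_rng(0)
        X = (rng.random((60, 4)) < 0.5).astype(float)
        design, terms, _ = build_design(X, 0, 3)
        assert design.shape[1] == 3 + 3  # 3 mains + C(3,2) products
        assert (1, 2) in terms and (1, 3) in terms and (2, 3) in terms
        col = terms.index((1, 2))
        assert np.array_equal(design[:, col], X[:, 1] * X[:, 2])

    def test_constant_column_excluded(self):
        X = np.column_stack(
            [np.array([0, 1, 0, 1] * 5), np.zeros(20), np.array([1, 0] * 10)]
        )
        design, terms, excluded = build_design(X, 2, 2)
        assert (1,) in excluded and (0,) in terms
        assert design.shape[1] == 1


class TestLambdaPath:
    def test_strictly_decreasing_of_requested_length(self):
        rng = np.random.default_rng(4)
        X, y = _random_instance(rng, 100, 3)
        path = lambda_path(X, y, n_lambda=20, lambda_min_ratio=0.05)
        assert len(path) == 20
        assert np.all(np.diff(path) < 0)
        assert path[0] == pytest.approx(lambda_max(X, y))

    def test_constant_response_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="constant"):
            lambda_path(X, np.ones(10))


class TestEBIC:
    def test_gamma_zero_is_bic(self):
        assert ebic(-100, 3, 1000, 31, 0.0) == pytest.approx(
            200 + 3 * np.log(1000)
        )

    def test_stated_arithmetic(self):
        val = ebic(-100, 3, 1000, 31, 0.25)
        assert val == pytest.approx(200 + 3 * np.log(1000) + 1.5 * np.log(31))
        assert val == pytest.approx(225.874, abs=5e-3)

    def test_df_zero_ignores_gamma(self):
        assert ebic(-50, 0, 500, 10, 0.7) == 100.0


def _toy_fit(logliks, dfs, lambdas=None):
    k = len(logliks)
    lambdas = np.geomspace(1.0, 0.01, k) if lambdas is None else np.asarray(lambdas)
    return NodewiseFit(
        node=0,
        terms=[(1,)] * 5,
        excluded_terms=[],
        lambda_path=lambdas,
        coef_path=np.zeros((k, 6)),
        loglik_path=np.asarray(logliks, float),
        df_path=np.asarray(dfs, int),
    )


class TestSelection:
    def test_unique_minimum_selected(self):
        logliks = -np.arange(10, 0, -1.0) * 10  # improving fit
        dfs = np.arange(10)
        fit = _toy_fit(logliks, dfs)
        lam = select_lambda(fit, "ebic", gamma=0.0, n=50)
        scores = [ebic(ll, df, 50, 5, 0.0) for ll, df in zip(logliks, dfs)]
        assert fit.selected_index == int(np.argmin(scores))
        assert lam == fit.lambda_path[fit.selected_index]

    def test_tie_goes_to_larger_lambda(self):
        fit = _toy_fit([-50.0, -50.0, -40.0], [2, 2, 9])
        select_lambda(fit, "ebic", gamma=0.25, n=100)
        assert fit.selected_index == 0

    def test_hand_computed_argmin(self):
        logliks = [-80.0, -60.0, -55.0, -54.5]
        dfs = [0, 1, 3, 5]
        n, d, gamma = 200, 5, 0.25
        scores = [ebic(ll, df, n, d, gamma) for ll, df in zip(logliks, dfs)]
        fit = _toy_fit(logliks, dfs)
        select_lambda(fit, "ebic", gamma=gamma, n=n)
        assert fit.selected_index == int(np.argmin(scores)) == 1

    def test_cv_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X, y = _random_instance(rng, 150, 3)
        lams = lambda_path(X, y, 10, 0.05)
        fits = []
        for _ in range(2):
            fit = fit_node_path(X, y, 0, [(1,), (2,), (3,)], [], EstimationConfig(), lams)
            select_lambda(fit, "cv", cv_folds=5, seed=9, design=X, response=y)
            fits.append(fit.selected_index)
        assert fits[0] == fits[1]


def _fit_with_pair_coef(node, coefs: dict):
    """NodewiseFit with selected coefficients for given pairwise terms."""
    terms = sorted(coefs)
    coef_row = np.concatenate([[0.0], [coefs[t] for t in terms]])
    fit = NodewiseFit(
        node=node,
        terms=terms,
        excluded_terms=[],
        lambda_path=np.array([1.0]),
        coef_path=coef_row[None, :],
        loglik_path=np.array([0.0]),
        df_path=np.array([0]),
        selected_index=0,
    )
    return fit


class TestAggregation:
    def test_and_edge_mean_weight_positive_sign(self):
        fits = [
            _fit_with_pair_coef(0, {(1,): 0.4}),
            _fit_with_pair_coef(1, {(0,): 0.6}),
        ]
        net = aggregate_network(fits, "and", ["a", "b"])
        assert net.weights[0, 1] == pytest.approx(0.5)
        assert net.sign_defined[0, 1]

    def test_or_edge_includes_zero_in_mean(self):
        fits = [
            _fit_with_pair_coef(0, {(1,): 0.4}),
            _fit_with_pair_coef(1, {(0,): 0.0}),
        ]
        assert aggregate_network(fits, "and", ["a", "b"]).edges() == set()
        net = aggregate_network(fits, "or", ["a", "b"])
        assert net.weights[0, 1] == pytest.approx(0.2)

    def test_sign_conflict_flagged(self):
        fits = [
            _fit_with_pair_coef(0, {(1,): 0.4}),
            _fit_with_pair_coef(1, {(0,): -0.6}),
        ]
        net = aggregate_network(fits, "and", ["a", "b"])
        assert net.weights[0, 1] == pytest.approx(0.5)
        assert not net.sign_defined[0, 1]


class TestFitMGM:
    def test_null_data_yields_nearly_no_edges(self):
        model = PlantedModel(
            np.zeros((10, 10)), np.full(10, -0.8), np.zeros(10, dtype=int)
        )
        cohort = sample_cohort(model, SimulationConfig(n=2000, seed=13))
        net = fit_mgm(cohort, EstimationConfig(gamma=0.25, seed=13))
        assert len(net.edges()) < 2

    def test_single_planted_edge_recovered_with_sign(self):
        theta = np.zeros((10, 10))
        theta[0, 1] = theta[1, 0] = 1.0
        model = PlantedModel(theta, np.full(10, -1.0), np.zeros(10, dtype=int))
        cohort = sample_cohort(model, SimulationConfig(n=2000, seed=21))
        net = fit_mgm(cohort, EstimationConfig(gamma=0.25, seed=21))
        assert (0, 1) in net.edges()
        assert net.weights[0, 1] > 0

    def test_and_subset_of_or(self, small_planted):
        _, cohort = small_planted
        net_and = fit_mgm(cohort, EstimationConfig(rule="and"))
        net_or = fit_mgm(cohort, EstimationConfig(rule="or"))
        assert net_and.edges() <= net_or.edges()

    def test_selected_df_non_increasing_in_gamma(self, small_planted):
        _, cohort = small_planted
        X = cohort.analysis_matrix().to_numpy(dtype=float)
        n, p = X.shape
        prev_dfs = None
        for gamma in (0.0, 0.25, 0.5):
            dfs = []
            for node in range(p):
                design, terms, excl = build_design(X, node, 2)
                fit = fit_node_path(
                    design, X[:, node], node, terms, excl,
                    EstimationConfig(gamma=gamma),
                )
                select_lambda(fit, "ebic", gamma=gamma, n=n)
                dfs.append(int(fit.df_path[fit.selected_index]))
            if prev_dfs is not None:
                assert all(d2 <= d1 for d1, d2 in zip(prev_dfs, dfs))
            prev_dfs = dfs

    def test_permutation_equivariance(self, small_planted):
        _, cohort = small_planted
        frame = cohort.analysis_matrix().iloc[:600]
        net = fit_mgm(frame, EstimationConfig())
        perm = np.random.default_rng(0).permutation(frame.shape[1])
        net_p = fit_mgm(frame.iloc[:, perm], EstimationConfig())
        assert np.allclose(net_p.weights, net.weights[np.ix_(perm, perm)])

    def test_k3_on_pairwise_data_yields_nearly_no_triples(self):
        model = PlantedModel(
            np.zeros((6, 6)), np.full(6, -0.5), np.zeros(6, dtype=int)
        )
        theta = model.theta.copy()
        theta[0, 1] = theta[1, 0] = 0.8
        model = PlantedModel(theta, model.alpha, model.blocks)
        cohort = sample_cohort(model, SimulationConfig(n=3000, seed=17))
        net = fit_mgm(cohort, EstimationConfig(k=3, gamma=0.25, seed=17))
        assert len(net.triples) <= 1

    def test_penalized_node_returns_loglik(self):
        rng = np.random.default_rng(8)
        X, y = _random_instance(rng, 120, 3)
        coef, ll = fit_penalized_node(X, y, 0.05)
        assert coef.shape == (4,)
        assert ll < 0
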