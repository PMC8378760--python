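"""Robust-fit solvers against grid-search and subgradient oracles."""

import numpy as np
import pytest

from droreg import (
    LAD,
    NormSpec,
    RegularizedLAD,
    WassersteinDRO,
    WDROConfig,
    fit_lad,
    fit_regularized_lad,
    fit_wdro,
    wdro_objective,
)
from droreg.datagen import RegressionData
from conftest import grid_search_wdro, random_instance


class TestObjective:
    def test_zero_coefficients(self, rng):
        data = random_instance(rng, p=3)
        for kind in ("l1", "l2", "linf"):
            cfg = WDROConfig(epsilon=0.7, norm=NormSpec(kind))
            expected = np.mean(np.abs(data.y)) + 0.7  # ||(0,1)||_* = 1
            assert wdro_objective(data, np.zeros(3), 0.0, cfg) == pytest.approx(expected)

    def test_interpolation_leaves_only_penalty(self):
        X = np.array([[1.0], [2.0]])
        data = RegressionData(X, X[:, 0] * 2.0)
        cfg = WDROConfig(epsilon=0.5, norm=NormSpec("l2"))
        assert wdro_objective(data, [2.0], 0.0, cfg) == pytest.approx(0.5 * np.sqrt(5))

    def test_matches_term_by_term_recomputation(self, rng):
        data = random_instance(rng, p=2, n=15)
        beta = rng.normal(size=2)
        b0 = rng.normal()
        eps = float(rng.uniform(0, 2))
        cfg = WDROConfig(epsilon=eps, norm=NormSpec("l2"))
        manual = sum(abs(y - b0 - x @ beta) for x, y in zip(data.X, data.y)) / data.n
        manual += eps * np.sqrt(beta @ beta + 1)
        assert wdro_objective(data, beta, b0, cfg) == pytest.approx(manual, abs=1e-12)


class TestFitWdro:
    def test_interpolation_with_zero_radius(self):
        data = RegressionData([[1.0], [2.0]], [1.0, 2.0])
        for kind in ("l1", "l2", "linf"):
            res = fit_wdro(data, WDROConfig(0.0, NormSpec(kind), fit_intercept=False))
            assert res.params[0] == pytest.approx(1.0, abs=1e-7)
            assert res.objective == pytest.approx(0.0, abs=1e-8)

    def test_linf_large_radius_kills_slope(self):
        # subgradient check: 0 is optimal since the loss slope at beta=0 is
        # within [-1, 1] scaled by the data, dominated by epsilon=2
        data = RegressionData([[1.0], [-1.0]], [1.0, -1.0])
        res = fit_wdro(data, WDROConfig(2.0, NormSpec("linf"), fit_intercept=False))
        assert res.params[0] == pytest.approx(0.0, abs=1e-9)
        assert res.objective == pytest.approx(3.0, abs=1e-8)

    def test_l2_small_radius_keeps_slope(self):
        data = RegressionData([[1.0], [-1.0]], [1.0, -1.0])
        res = fit_wdro(data, WDROConfig(0.1, NormSpec("l2"), fit_intercept=False))
        assert res.params[0] == pytest.approx(1.0, abs=1e-5)
        assert res.objective == pytest.approx(0.1 * np.sqrt(2), abs=1e-7)

    @pytest.mark.parametrize("kind", ["l1", "l2", "linf", "weighted"])
    def test_matches_grid_oracle(self, rng, kind):
        for _ in range(25):
            data = random_instance(rng, n=15)
            M = None
            if kind == "weighted":
                d = np.concatenate([rng.uniform(0.5, 2.0, data.p), [1.0]])
                M = np.diag(d)
            cfg = WDROConfig(float(rng.uniform(0.05, 1.0)), NormSpec(kind, M=M),
                             fit_intercept=bool(rng.integers(2)))
            res = fit_wdro(data, cfg)
            assert res.status == "optimal"
            _, f_grid = grid_search_wdro(data, cfg)
            assert res.objective <= f_grid + 1e-4

    def test_objective_consistent_with_definition(self, rng):
        data = random_instance(rng, p=4, n=30)
        cfg = WDROConfig(0.3, NormSpec("l2"))
        res = fit_wdro(data, cfg)
        assert res.objective == pytest.approx(
            wdro_objective(data, res.params, res.intercept, cfg), abs=1e-9
        )

    def test_weighted_identity_reproduces_l2(self, rng):
        data = random_instance(rng, p=3, n=25)
        r2 = fit_wdro(data, WDROConfig(0.4, NormSpec("l2")))
        rw = fit_wdro(data, WDROConfig(0.4, NormSpec("weighted", M=np.eye(4))))
        assert np.allclose(r2.params, rw.params, atol=1e-6)
        assert r2.objective == pytest.approx(rw.objective, abs=1e-8)

    def test_l1_ball_constraint_binds(self, rng):
        data = random_instance(rng, p=3, n=40, noise=0.05)
        free = fit_wdro(data, WDROConfig(0.01, NormSpec("l2")))
        l = 0.5 * np.sum(np.abs(free.params))
        capped = fit_wdro(data, WDROConfig(0.01, NormSpec("l2"), l1_ball=l))
        assert np.sum(np.abs(capped.params)) <= l + 1e-6
        capped_lp = fit_wdro(data, WDROConfig(0.01, NormSpec("l1"), l1_ball=l))
        assert np.sum(np.abs(capped_lp.params)) <= l + 1e-6

    def test_loss_monotone_in_radius(self, rng):
        # more ambiguity -> the fit trades training loss for a smaller penalty
        data = random_instance(rng, p=2, n=40)
        losses, penalties = [], []
        for eps in np.linspace(0.0, 1.0, 20):
            cfg = WDROConfig(eps, NormSpec("l2"))
            res = fit_wdro(data, cfg)
            losses.append(np.mean(np.abs(res.resid(data.X, data.y))))
            penalties.append(np.sqrt(res.params @ res.params + 1))
        assert np.all(np.diff(losses) >= -1e-7)
        assert np.all(np.diff(penalties) <= 1e-7)


class TestLad:
    def test_intercept_only_fits_median(self):
        data = RegressionData(np.zeros((3, 1)), [-1.0, 0.0, 1.0])
        res = fit_lad(data)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)

    def test_zero_objective_on_linear_data(self, rng):
        X = rng.normal(size=(10, 2))
        data = RegressionData(X, X @ [1.0, -2.0] + 0.5)
        assert fit_lad(data).objective == pytest.approx(0.0, abs=1e-9)

    def test_equals_zero_radius_wdro(self, rng):
        for _ in range(30):
            data = random_instance(rng, n=12)
            fi = bool(rng.integers(2))
            a = fit_lad(data, fit_intercept=fi)
            b = fit_wdro(data, WDROConfig(0.0, NormSpec("l1"), fit_intercept=fi))
            assert a.objective == pytest.approx(b.objective, abs=1e-8)


class TestRegularizedLad:
    def test_zero_penalty_equals_lad(self, rng):
        data = random_instance(rng, p=2, n=20)
        for pen in ("l1", "l2"):
            r = fit_regularized_lad(data, pen, 0.0)
            assert r.objective == pytest.approx(fit_lad(data).objective, abs=1e-7)

    def test_l1_penalty_offsets_linf_metric_by_epsilon(self, rng):
        # penalizing (-beta, 1) under the l-inf metric only adds the constant
        # epsilon relative to penalizing beta alone
        for _ in range(25):
            data = random_instance(rng, n=15)
            eps = float(rng.uniform(0.05, 0.8))
            a = fit_wdro(data, WDROConfig(eps, NormSpec("linf")))
            b = fit_regularized_lad(data, "l1", eps)
            assert a.objective - b.objective == pytest.approx(eps, abs=1e-6)

    def test_l2_dominant_penalty_gives_exact_zero(self, rng):
        data = random_instance(rng, p=3, n=25)
        lam = 2.0 * max(np.linalg.norm(x) for x in data.X)
        res = fit_regularized_lad(data, "l2", lam)
        assert np.array_equal(res.params, np.zeros(3))

    def test_l2_matches_perturbation_search(self, rng):
        data = random_instance(rng, p=2, n=20)
        res = fit_regularized_lad(data, "l2", 0.1)
        model = RegularizedLAD(data.y, data.X, penalty="l2", lam=0.1)
        base = model._objective(res.params, res.intercept)
        for _ in range(500):
            cand = model._objective(
                res.params + rng.normal(scale=1e-3, size=2),
                res.intercept + rng.normal(scale=1e-3),
            )
            assert cand >= base - 1e-9


class TestWeightedLimit:
    def test_large_response_cost_approaches_l2_regularized_lad(self, rng):
        # M = diag(1,...,1,c^2): as c grows the extended penalty collapses to
        # a pure l2 penalty on the slope
        # a radius large enough that the penalty actually shapes the solution
        # (at small radii the piecewise-linear loss pins the same vertex for
        # every c and the limit is attained exactly)
        data = random_instance(rng, p=2, n=30)
        eps = 1.0
        target = fit_regularized_lad(data, "l2", eps)
        gaps = []
        for c in (1.0, 10.0, 100.0, 1000.0):
            M = np.diag([1.0, 1.0, c**2])
            res = fit_wdro(data, WDROConfig(eps, NormSpec("weighted", M=M)))
            gaps.append(np.linalg.norm(res.params - target.params))
        assert np.all(np.diff(gaps) < 0)
        assert gaps[-1] < 1e-2 * gaps[0]


class TestRecoveryRate:
    def test_error_shrinks_with_sample_size(self):
        # clean data: estimation error should drop roughly as 1/sqrt(N)
        from droreg import ScenarioSpec, generate_dataset

        errors = {100: [], 2000: []}
        for rep in range(8):
            for n in errors:
                spec = ScenarioSpec("dense_xy", q=0.0, rho=0.3, snr=2.0,
                                    n_train=n, n_test=0, seed=1000 + rep)
                train, _ = generate_dataset(spec)
                res = fit_wdro(train, WDROConfig(0.01, NormSpec("l1")))
                errors[n].append(np.linalg.norm(res.params - train.truth.beta_star))
        assert np.median(errors[2000]) < np.median(errors[100])
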