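"""Generator correctness: covariance construction, mixtures, reproducibility."""

import numpy as np
import pytest
from scipy import stats

from droreg import (
    ScenarioSpec,
    build_sigma,
    gamma_matrix,
    generate_cloud_dataset,
    generate_dataset,
    sigma_from_snr,
)
from droreg.datagen import CLOUD_BETA, CLOUD_INTERCEPT, SPARSE_BETA


class TestBuildSigma:
    def test_zero_correlation_is_identity(self):
        assert np.array_equal(build_sigma(2, 0.0), np.eye(2))

    def test_off_diagonal_value(self):
        np.testing.assert_allclose(build_sigma(2, 0.5), [[1, 0.5], [0.5, 1]])

    @pytest.mark.parametrize("p,rho", [(3, -1.0), (3, -0.6), (2, 1.0), (4, 1.5)])
    def test_non_pd_range_rejected(self, p, rho):
        with pytest.raises(ValueError):
            build_sigma(p, rho)


class TestSigmaFromSnr:
    def test_unit_quadratic_form(self):
        assert sigma_from_snr([1.0, 0.0], np.eye(2), 1.0) == pytest.approx(1.0)

    def test_compound_symmetric_value(self):
        # quadratic form evaluated by direct matrix arithmetic:
        # 0.25 * (20 + 380 * 0.25) = 28.75, sigma = sqrt(28.75 / 0.5)
        beta = np.full(20, 0.5)
        Sigma = build_sigma(20, 0.25)
        expected = np.sqrt(float(beta @ Sigma @ beta) / 0.5)
        assert expected == pytest.approx(np.sqrt(57.5))
        assert sigma_from_snr(beta, Sigma, 0.5) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sigma_from_snr([1.0], np.eye(1), 0.0)
        with pytest.raises(ValueError):
            sigma_from_snr(np.zeros(3), np.eye(3), 1.0)


class TestGammaMatrix:
    def test_scalar_substitution(self):
        np.testing.assert_allclose(
            gamma_matrix(np.eye(1), [2.0], 1.0), [[1, 2], [2, 5]]
        )

    def test_zero_beta_block_diagonal(self):
        G = gamma_matrix(np.eye(3), np.zeros(3), 2.0)
        np.testing.assert_allclose(G[:3, 3], 0)
        assert G[3, 3] == pytest.approx(4.0)

    def test_positive_definite_assembly(self):
        G = gamma_matrix(build_sigma(3, 0.5), np.ones(3), 2.0)
        assert np.all(np.linalg.eigvalsh(G) > 0)
        np.testing.assert_allclose(G, G.T)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            gamma_matrix(np.eye(2), np.ones(2), 0.0)


def _spec(**kw):
    base = dict(family="dense_xy", q=0.3, rho=0.3, snr=0.5, n_train=100,
                n_test=20, seed=7)
    base.update(kw)
    return ScenarioSpec(**base)


class TestScenarioSpec:
    def test_exactly_one_noise_parameter(self):
        with pytest.raises(ValueError):
            _spec(sigma=1.0)
        with pytest.raises(ValueError):
            _spec(snr=None)

    def test_majority_contamination_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="droreg.datagen"):
            _spec(q=0.6)
        assert any("0.5" in r.message for r in caplog.records)


class TestGenerateDataset:
    def test_no_contamination_means_no_labels(self):
        train, _ = generate_dataset(_spec(q=0.0))
        assert not train.labels.any()

    def test_outlier_count_binomial_concentration(self):
        train, _ = generate_dataset(_spec(q=0.3, n_train=1000))
        count = train.labels.sum()
        assert abs(count - 300) <= 3 * np.sqrt(1000 * 0.3 * 0.7)

    def test_sparse_truth_coefficients(self):
        train, _ = generate_dataset(_spec(family="sparse_xy"))
        assert np.count_nonzero(train.truth.beta_star) == 4
        assert train.truth.intercept_star == pytest.approx(3.0)
        np.testing.assert_allclose(train.truth.beta_star, SPARSE_BETA)

    def test_test_split_is_clean(self):
        _, test = generate_dataset(_spec(q=0.4, n_test=50))
        assert not test.labels.any()

    def test_bit_reproducible(self):
        a, at = generate_dataset(_spec())
        b, bt = generate_dataset(_spec())
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)
        assert np.array_equal(at.X, bt.X)

    def test_cloud_family_redirects(self):
        with pytest.raises(ValueError, match="cloud"):
            generate_dataset(_spec(family="cloud", rho=0.0))

    def test_clean_moments_match_truth(self):
        # empirical covariance and SNR of clean rows at large n
        train, _ = generate_dataset(_spec(q=0.0, n_train=50_000, n_test=0))
        emp = np.cov(train.X.T)
        assert np.max(np.abs(emp - train.truth.Sigma)) < 0.05
        signal = train.truth.beta_star @ emp @ train.truth.beta_star
        resid = train.y - train.truth.intercept_star - train.X @ train.truth.beta_star
        snr_hat = signal / np.var(resid)
        assert abs(snr_hat - 0.5) / 0.5 < 0.10

    def test_xy_families_shift_response(self):
        train, _ = generate_dataset(_spec(family="dense_xy", q=0.3, n_train=2000))
        t = train.truth
        resid = train.y - t.intercept_star - train.X @ t.beta_star
        # contaminated rows carry a +5 sigma mean shift in the response
        assert resid[train.labels].mean() == pytest.approx(5 * t.sigma, rel=0.1)
        train_x, _ = generate_dataset(_spec(family="dense_x", q=0.3, n_train=2000))
        resid_x = (
            train_x.y
            - train_x.truth.intercept_star
            - train_x.X @ train_x.truth.beta_star
        )
        assert abs(resid_x[train_x.labels].mean()) < 0.5 * train_x.truth.sigma


class TestCloudDataset:
    def test_outlier_rows_are_tight_clusters(self):
        data = generate_cloud_dataset(400, 0.3, 0.5, 2.5, seed=3)
        spread = data.X[data.labels].max(axis=1) - data.X[data.labels].min(axis=1)
        assert np.all(spread <= 0.25)

    def test_outlier_response_offset_is_exact(self):
        data = generate_cloud_dataset(400, 0.3, 0.5, 2.5, seed=3)
        plane = CLOUD_INTERCEPT + data.X @ CLOUD_BETA
        np.testing.assert_allclose(data.y[data.labels] - plane[data.labels], 2.5)

    def test_clean_noise_is_gaussian(self):
        data = generate_cloud_dataset(500, 0.0, 0.5, 2.5, seed=11)
        resid = data.y - (CLOUD_INTERCEPT + data.X @ CLOUD_BETA)
        assert stats.shapiro(resid).pvalue > 0.01
        assert np.std(resid) == pytest.approx(0.5, rel=0.15)
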