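import numpy as np
import pytest
from scipy import stats

from habiquant import (
    ParamEstimates,
    PathModel,
    default_model,
    effect_decomposition,
    fit_ml,
    generate_sem_table,
    implied_covariance,
    load_reported_path_coefficients,
    rank_normalize,
    structural_model_from_paths,
    total_effects_matrix,
    SemTruth,
)


class TestRankNormalize:
    def test_monotone_preserves_order(self):
        x = np.array([3.0, 1.0, 10.0, 2.0, 7.0])
        y = rank_normalize(x)
        assert np.array_equal(np.argsort(y), np.argsort(x))

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        y = rank_normalize(rng.lognormal(size=500))
        assert abs(y.mean()) < 1e-9
        assert abs(y.std() - 1.0) < 1e-9

    def test_normalizes_skewed_sample(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(sigma=1.5, size=1000)
        assert abs(stats.skew(x)) > 2.0
        assert abs(stats.skew(rank_normalize(x))) < 0.05

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            rank_normalize(np.ones(10))


class TestPathModelValidation:
    def test_single_indicator_latent_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            PathModel(latents={"L": ["a"]}, observed_structural=["HQ"], paths=[])

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            PathModel(
                observed_structural=["A", "B"], paths=[("A", "B"), ("B", "A")]
            )

    def test_response_may_not_emit(self):
        with pytest.raises(ValueError, match="HQ"):
            PathModel(observed_structural=["HQ", "X"], paths=[("HQ", "X")])

    def test_indicator_on_two_latents_rejected(self):
        with pytest.raises(ValueError, match="loads on both"):
            PathModel(
                latents={"L1": ["a", "b"], "L2": ["a", "c"]},
                observed_structural=[],
                paths=[],
            )


class TestImpliedCovariance:
    def test_null_model_gives_residual_diagonal(self):
        model = PathModel(observed_structural=["A", "B"], paths=[])
        params = ParamEstimates(
            loadings={}, structural={}, psi={"A": 2.0, "B": 3.0}, theta={}
        )
        sigma = implied_covariance(model, params)
        np.testing.assert_allclose(sigma, np.diag([2.0, 3.0]))

    def test_single_latent_cross_covariance_is_lambda_phi(self):
        model = PathModel(latents={"L": ["y1", "y2"]}, observed_structural=[], paths=[])
        params = ParamEstimates(
            loadings={"y1": 1.0, "y2": 0.7},
            structural={},
            psi={"L": 2.0},
            theta={"y1": 0.5, "y2": 0.5},
        )
        sigma = implied_covariance(model, params)
        assert sigma[0, 1] == pytest.approx(0.7 * 2.0)

    def test_symmetric(self):
        truth = SemTruth()
        sigma = truth.implied_cov()
        np.testing.assert_allclose(sigma, sigma.T, atol=1e-12)
        assert np.linalg.eigvalsh(sigma).min() > 0


class TestFitML:
    def test_parameter_recovery_on_generated_data(self):
        truth = SemTruth(n=5000, seed=42)
        table = generate_sem_table(truth)
        params, fit = fit_ml(table.cov(), n=truth.n, model=truth.model, seed=0)
        for edge, true_val in truth.paths.items():
            assert params.standardized_paths[edge] == pytest.approx(true_val, abs=0.05)
        for ind, lam in truth.loadings.items():
            assert abs(params.standardized_loadings[ind]) == pytest.approx(abs(lam), abs=0.05)

    def test_true_model_passes_fit_gates(self):
        truth = SemTruth(n=5000, seed=42)
        table = generate_sem_table(truth)
        _, fit = fit_ml(table.cov(), n=truth.n, model=truth.model, seed=0)
        assert fit.cfi > 0.90
        assert fit.gfi > 0.90
        assert fit.rmsea < 0.06
        assert fit.srmr < 0.05

    def test_population_covariance_fits_exactly(self):
        # feeding the truth's own implied covariance: chi2 ~ 0, indices saturate
        truth = SemTruth()
        sigma = truth.implied_cov()
        params, fit = fit_ml(sigma, n=10_000, model=truth.model, seed=0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-3)
        assert fit.cfi == pytest.approx(1.0, abs=1e-4)
        assert fit.srmr == pytest.approx(0.0, abs=1e-4)
        assert fit.rmsea == pytest.approx(0.0, abs=1e-3)

    def test_non_pd_covariance_rejected(self):
        truth = SemTruth()
        p = len(truth.model.observed)
        with pytest.raises(ValueError, match="positive-definite"):
            fit_ml(np.zeros((p, p)), n=100, model=truth.model)

    def test_discrepancy_not_worse_than_start(self):
        truth = SemTruth(n=2000, seed=5)
        table = generate_sem_table(truth)
        params, fit = fit_ml(table.cov(), n=truth.n, model=truth.model, seed=0)
        # the saturated-model df bound: fitted chi2 must be non-negative and finite
        assert 0.0 <= fit.chi2 < 1e4


class TestEffectDecomposition:
    def test_single_edge_direct_only(self):
        model = PathModel(observed_structural=["X", "HQ"], paths=[("X", "HQ")])
        row = effect_decomposition(model, {("X", "HQ"): 0.4}, "X", "HQ")
        assert row.direct == pytest.approx(0.4)
        assert row.indirect == []
        assert row.total == pytest.approx(0.4)

    def test_chain_products(self):
        model = PathModel(
            observed_structural=["X", "M", "HQ"],
            paths=[("X", "M"), ("M", "HQ"), ("X", "HQ")],
        )
        coefs = {("X", "M"): 0.5, ("M", "HQ"): 0.4, ("X", "HQ"): 0.1}
        row = effect_decomposition(model, coefs, "X", "HQ")
        assert row.direct == pytest.approx(0.1)
        assert row.indirect_total == pytest.approx(0.2)
        assert row.total == pytest.approx(0.3)

    def test_total_equals_direct_plus_sum_of_indirect(self):
        coefs = load_reported_path_coefficients()[2018]
        model = structural_model_from_paths(coefs)
        row = effect_decomposition(model, coefs, "Topography")
        assert row.total == pytest.approx(row.direct + sum(v for _, v in row.indirect))

    @pytest.mark.parametrize("year", [2000, 2010, 2018, 2020])
    def test_agrees_with_reduced_form_matrix(self, year):
        coefs = load_reported_path_coefficients()[year]
        model = structural_model_from_paths(coefs)
        totals = total_effects_matrix(model, coefs)
        for driver in model.structural_nodes:
            if driver == "HQ":
                continue
            row = effect_decomposition(model, coefs, driver, "HQ")
            assert row.total == pytest.approx(totals.loc["HQ", driver], abs=1e-12)

    def test_fitted_model_decomposition_consistency(self):
        truth = SemTruth(n=5000, seed=9)
        table = generate_sem_table(truth)
        params, _ = fit_ml(table.cov(), n=truth.n, model=truth.model, seed=0)
        totals = total_effects_matrix(truth.model, params)
        row = effect_decomposition(truth.model, params, "Topography", "HQ")
        assert row.total == pytest.approx(totals.loc["HQ", "Topography"], abs=1e-12)
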