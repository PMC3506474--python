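"""ML estimation: discrepancy, recovery, chi-square difference, Heywood flags."""

import numpy as np
import pytest

from singlesem import (
    ChainWorld,
    FitOptions,
    ModelError,
    NestingError,
    ParamCell,
    SampleMoments,
    SemModel,
    chisq_difference,
    compensating_estimate,
    fit_ml,
    implied_covariance,
)
from singlesem.estimate import check_nested
from singlesem.fixtures import (
    saturated_pairs_model,
    structured_pairs_model,
    structured_pairs_population,
)
from singlesem.simulate import chain_identity_model, chain_world_moments


def saturated_free_model(p):
    """One pseudo-latent per indicator, all moments free: df = 0."""
    model = SemModel([f"e{i}" for i in range(p)], [f"y{i}" for i in range(p)])
    for i in range(p):
        model.set_loading(f"y{i}", f"e{i}", ParamCell("fixed", 1.0))
        for j in range(i + 1):
            model.set_psi(f"e{j}", f"e{i}", ParamCell("free", None))
    return model


class TestFitML:
    def test_saturated_model_fits_exactly(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(4, 8))
        S = A @ A.T / 8
        moments = SampleMoments(S, 200, [f"y{i}" for i in range(4)])
        fit = fit_ml(saturated_free_model(4), moments)
        assert fit.df == 0
        assert fit.F_ML < 1e-10
        assert fit.chisq < 1e-7
        np.testing.assert_allclose(
            implied_covariance(fit.model, fit.theta_hat).Sigma, S, atol=1e-6
        )

    def test_population_self_consistency(self, structured_model, structured_truth, structured_pop):
        """Fitting a model to its own population moments recovers the
        generating parameters essentially exactly."""
        fit = fit_ml(structured_model, structured_pop)
        assert fit.converged
        assert fit.F_ML < 1e-10
        for name, value in structured_truth.items():
            assert fit.estimate(name) == pytest.approx(value, abs=1e-4)

    def test_identity_misspecification_matches_compensating_estimate(self, world):
        """Population fit under the wrong latent identity reproduces the
        closed-form compensating loading exactly."""
        for identity in ("A", "B", "C"):
            model = chain_identity_model(world, identity)
            fit = fit_ml(model, chain_world_moments(world, N=1000))
            lam = fit.estimate(f"load:y6~eta3{identity}")
            assert lam == pytest.approx(compensating_estimate(world, identity), abs=1e-5)

    def test_indicator_reordering_equivariance(self, structured_model, structured_pop):
        fit = fit_ml(structured_model, structured_pop)
        perm = [3, 7, 0, 5, 1, 6, 2, 4]
        S = structured_pop.S[np.ix_(perm, perm)]
        names = [structured_pop.variable_names[i] for i in perm]
        fit2 = fit_ml(structured_model, SampleMoments(S, structured_pop.N, names))
        assert fit2.param_names == fit.param_names
        np.testing.assert_allclose(fit2.theta_hat, fit.theta_hat, atol=1e-6)

    def test_chisq_multiplier_convention(self, structured_model):
        # perturb one moment so the discrepancy is nonzero
        mom = structured_pairs_population(N=101)
        S = mom.S.copy()
        S[0, 1] = S[1, 0] = S[0, 1] + 0.1
        m100 = SampleMoments(S, 101, mom.variable_names)
        fit_nm1 = fit_ml(structured_model, m100, FitOptions(chisq_multiplier="n-1"))
        fit_n = fit_ml(structured_model, m100, FitOptions(chisq_multiplier="n"))
        assert fit_nm1.chisq == pytest.approx(100 * fit_nm1.F_ML)
        assert fit_n.chisq == pytest.approx(101 * fit_n.F_ML)
        assert fit_nm1.F_ML == pytest.approx(fit_n.F_ML, rel=1e-8)

    def test_heywood_case_flagged_not_clipped(self):
        # classic one-factor Heywood construction: theta1 = s11 - s12*s13/s23
        # is negative for this (positive definite) covariance matrix
        model = SemModel(["e"], ["y1", "y2", "y3"])
        model.set_loading("y1", "e", ParamCell("fixed", 1.0))
        model.set_loading("y2", "e", ParamCell("free", None))
        model.set_loading("y3", "e", ParamCell("free", None))
        model.set_psi("e", "e", ParamCell("free", None))
        for y in ("y1", "y2", "y3"):
            model.set_theta(y, y, ParamCell("free", None))
        S = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.8], [0.9, 0.8, 1.0]])
        fit = fit_ml(model, SampleMoments(S, 200, ["y1", "y2", "y3"]))
        assert fit.heywood
        assert fit.estimate("theta:y1,y1") == pytest.approx(1 - 0.9 * 0.9 / 0.8, abs=1e-4)

    def test_non_pd_sample_matrix_rejected(self, structured_model):
        S = np.zeros((8, 8))
        moments = SampleMoments(S, 100, structured_model.indicator_names)
        with pytest.raises(ModelError, match="positive definite"):
            fit_ml(structured_model, moments)

    def test_under_determined_model_refused(self):
        model = SemModel(["e"], ["y"])
        model.set_loading("y", "e", ParamCell("fixed", 1.0))
        model.set_psi("e", "e", ParamCell("free", None))
        model.set_theta("y", "y", ParamCell("free", None))
        moments = SampleMoments(np.array([[2.0]]), 100, ["y"])
        with pytest.raises(ModelError, match="under-determined"):
            fit_ml(model, moments)

    def test_standard_errors_shrink_with_n(self, structured_model):
        se_small = fit_ml(structured_model, structured_pairs_population(N=200)).se
        se_big = fit_ml(structured_model, structured_pairs_population(N=5000)).se
        assert se_small is not None and se_big is not None
        assert np.all(se_big < se_small)
        np.testing.assert_allclose(se_big * np.sqrt(4999 / 199), se_small, rtol=1e-6)


class TestChisqDifference:
    def test_structured_nested_in_saturated(self, structured_pop):
        fit_r = fit_ml(structured_pairs_model(), structured_pop)
        fit_u = fit_ml(saturated_pairs_model(), structured_pop)
        diff = chisq_difference(fit_r, fit_u)
        # 2 latent-level restrictions + 4 fixed error variances
        assert diff.delta_df == 6
        assert diff.delta_chisq == pytest.approx(0.0, abs=1e-6)
        assert diff.p_value == pytest.approx(1.0)

    def test_identical_models_rejected(self, structured_pop):
        fit = fit_ml(structured_pairs_model(), structured_pop)
        with pytest.raises(NestingError, match="no degrees of freedom"):
            chisq_difference(fit, fit)

    def test_different_moments_rejected(self, structured_pop):
        fit_r = fit_ml(structured_pairs_model(), structured_pop)
        other = SampleMoments(structured_pop.S * 1.01, 500, structured_pop.variable_names)
        fit_u = fit_ml(saturated_pairs_model(), other)
        with pytest.raises(NestingError, match="different sample moments"):
            chisq_difference(fit_r, fit_u)

    def test_non_nested_fixed_values_rejected(self, structured_pop):
        restricted = structured_pairs_model()
        unrestricted = structured_pairs_model()
        cell = unrestricted.Theta[0, 0]
        cell.value = 0.9  # same cell fixed at a different value
        assert not check_nested(restricted, unrestricted)[0]
        fit_r = fit_ml(restricted, structured_pop)
        fit_u = fit_ml(unrestricted, structured_pop, FitOptions())
        with pytest.raises(NestingError, match="not nested"):
            chisq_difference(fit_r, fit_u)

    def test_truth_restriction_costs_nothing_at_population(self, structured_pop, structured_truth):
        """Fixing one parameter at its generating value leaves chi-square at
        zero on population moments."""
        restricted = structured_pairs_model()
        restricted.set_effect("eta3", "eta4", ParamCell("fixed", structured_truth["effect:eta3->eta4"]))
        fit_r = fit_ml(restricted, structured_pop)
        fit_u = fit_ml(structured_pairs_model(), structured_pop)
        diff = chisq_difference(fit_r, fit_u)
        assert diff.delta_df == 1
        assert diff.delta_chisq == pytest.approx(0.0, abs=1e-6)
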