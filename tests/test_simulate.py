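"""Synthetic data, assignment rules, and identity experiments."""

import numpy as np
import pytest

from singlesem import (
    ChainWorld,
    IdentityExperiment,
    InvalidAssignmentError,
    ParamCell,
    SemModel,
    assignment_rules,
    compensating_estimate,
    run_identity_experiment,
    simulate_data,
)
from singlesem.model import ModelError
from singlesem.simulate import chain_world_embedding


class TestSimulateData:
    def test_error_free_limit_converges_to_psi(self):
        model = SemModel(["e1", "e2"], ["y1", "y2"])
        Psi = np.array([[1.0, 0.4], [0.4, 2.0]])
        for k, (a, b) in enumerate([("y1", "e1"), ("y2", "e2")]):
            model.set_loading(a, b, ParamCell("fixed", 1.0))
        model.set_psi("e1", "e1", ParamCell("fixed", 1.0))
        model.set_psi("e2", "e2", ParamCell("fixed", 2.0))
        model.set_psi("e1", "e2", ParamCell("fixed", 0.4))
        sm = simulate_data(model, None, n=200000, seed=2, return_moments=True)
        np.testing.assert_allclose(sm.S, Psi, atol=0.05)

    def test_seed_reproducibility_and_independence(self, world):
        emb = chain_world_embedding(world)
        a = simulate_data(emb, None, n=500, seed=9)
        b = simulate_data(emb, None, n=500, seed=9)
        c = simulate_data(emb, None, n=500, seed=10)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_zero_or_missing_inputs_rejected(self, world):
        emb = chain_world_embedding(world)
        with pytest.raises(ValueError, match="positive"):
            simulate_data(emb, None, n=0, seed=1)
        with pytest.raises(ValueError, match="seed"):
            simulate_data(emb, None, n=10)

    def test_non_psd_psi_rejected(self):
        model = SemModel(["e1", "e2"], ["y1", "y2"])
        model.set_loading("y1", "e1", ParamCell("fixed", 1.0))
        model.set_loading("y2", "e2", ParamCell("fixed", 1.0))
        model.set_psi("e1", "e1", ParamCell("fixed", 1.0))
        model.set_psi("e2", "e2", ParamCell("fixed", 1.0))
        model.set_psi("e1", "e2", ParamCell("fixed", 2.0))  # |cov| > sqrt(var*var)
        with pytest.raises(ModelError, match="positive semi-definite"):
            simulate_data(model, None, n=10, seed=1)


class TestAssignmentRules:
    """The full truth table of justifiable indicator-to-latent assignments."""

    @pytest.mark.parametrize(
        "design, identity, valid",
        [
            ("y5_single", "A", True),
            ("y5_single", "B", True),
            ("y5_single", "C", True),
            ("y6_single", "A", True),
            ("y6_single", "B", True),
            ("y6_single", "C", False),  # error-C sources never cause y6
            ("multiple", "A", False),
            ("multiple", "B", True),  # only the common cause of both
            ("multiple", "C", False),
        ],
    )
    def test_single_identity_designs(self, design, identity, valid):
        verdict = assignment_rules(design, identity)
        assert verdict.valid is valid
        assert verdict.reason

    @pytest.mark.parametrize(
        "pair, valid",
        [
            (("C", "B"), True),  # the one coherent two-latent reading
            (("A", "B"), False),
            (("B", "A"), False),
            (("C", "A"), False),
            (("B", "C"), False),
            (("A", "C"), False),
            (("A", "A"), False),
            (("B", "B"), False),
            (("C", "C"), False),
        ],
    )
    def test_both_single_pairs(self, pair, valid):
        assert assignment_rules("both_single", pair).valid is valid

    def test_rules_are_pure_and_total(self):
        # every combination returns a verdict with a reason, never raises
        for design in ("y5_single", "y6_single", "multiple"):
            for identity in ("A", "B", "C", "Z"):
                v = assignment_rules(design, identity)
                assert isinstance(v.valid, bool) and v.reason
        for a in "ABC":
            for b in "ABC":
                v = assignment_rules("both_single", (a, b))
                assert isinstance(v.valid, bool) and v.reason
        assert not assignment_rules("nonsense", "B").valid


class TestIdentityExperiment:
    def test_population_identity_b_unbiased(self, world):
        exp = IdentityExperiment(world=world, chosen_identity="B", design="multiple")
        res = run_identity_experiment(exp)
        assert res.lambda6_hat == pytest.approx(world.lambda6, abs=1e-5)
        assert res.bias == pytest.approx(0.0, abs=1e-5)

    def test_population_identity_c_attenuated(self, world):
        exp = IdentityExperiment(world=world, chosen_identity="C", design="multiple")
        res = run_identity_experiment(exp, allow_invalid=True)
        assert res.lambda6_hat == pytest.approx(0.6, abs=1e-5)
        assert res.bias == pytest.approx(-0.2, abs=1e-5)

    def test_invalid_assignment_needs_explicit_flag(self, world):
        exp = IdentityExperiment(world=world, chosen_identity="C", design="multiple")
        with pytest.raises(InvalidAssignmentError):
            run_identity_experiment(exp)

    def test_population_bias_matches_closed_form_on_grid(self):
        """Across a grid of worlds, the fitted loading under every identity
        equals the path-tracing compensating estimate."""
        for err_b in (0.25, 0.5, 1.0):
            for err_c in (0.25, 0.5, 1.0):
                for lam6 in (0.4, 0.8, 1.2):
                    world = ChainWorld(var_errorB=err_b, var_errorC=err_c, lambda6=lam6)
                    for identity in ("A", "B", "C"):
                        exp = IdentityExperiment(world=world, chosen_identity=identity,
                                                 design="multiple")
                        res = run_identity_experiment(exp, allow_invalid=True)
                        expected = compensating_estimate(world, identity)
                        assert res.lambda6_hat == pytest.approx(expected, abs=1e-6), (
                            err_b, err_c, lam6, identity,
                        )

    def test_zero_true_effect_still_estimated_nonzero_under_wrong_identity(self):
        """A world where the downstream latent truly has no effect on y6:
        choosing it anyway yields a spuriously nonzero loading (pure bias)."""
        world = ChainWorld(lambda6=0.8)
        exp = IdentityExperiment(world=world, chosen_identity="C", design="multiple")
        res = run_identity_experiment(exp, allow_invalid=True)
        # the generating model has no C -> y6 effect at all, so any nonzero
        # estimate for the C-identified latent's loading is bias
        assert abs(res.lambda6_hat) > 0.1

    def test_monte_carlo_bias_near_population_bias(self, world):
        reps, n = 40, 2000
        pop_bias = compensating_estimate(world, "C") - world.lambda6
        biases = []
        for r in range(reps):
            exp = IdentityExperiment(world=world, chosen_identity="C", design="multiple",
                                     mode="monte_carlo", n=n, seed=1000 + r)
            biases.append(run_identity_experiment(exp, allow_invalid=True).bias)
        mc_bias = np.mean(biases)
        mc_se = np.std(biases, ddof=1) / np.sqrt(reps)
        assert abs(mc_bias - pop_bias) < 3 * mc_se + 1e-12
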