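"""Additive and interaction CNMA fitting, additivity test, nested models."""

import numpy as np
import pytest

from cnma import (
    Contrast,
    IdentificationError,
    Network,
    UsageError,
    add_interactions,
    additivity_test,
    build_combination,
    compare_nested,
    fit_cnma,
    fit_nma,
    q_cnma,
)
from conftest import hypothetical_network

TABLE1_D = [1.0, 2.0, 0.0, 1.0, 1.0, 1.0]
TABLE1_XA = np.array(
    [
        [0, -1, 0],
        [0, -1, -1],
        [1, 0, -1],
        [0, 0, -1],
        [-1, 0, 0],
        [1, 0, 0],
    ],
    dtype=float,
)


class TestFitCnma:
    def test_single_study_component_effect(self):
        net = Network([Contrast("s", "A", "Placebo", 0.5, 1.0)])
        comps = build_combination(net.treatments, "+", inactive="Placebo")
        fit = fit_cnma(net, comps)
        assert fit.beta_hat[0] == pytest.approx(0.5)
        assert fit.cov_beta[0, 0] == pytest.approx(1.0)

    def test_hypothetical_matches_normal_equations_oracle(self):
        """With unit weights, beta_hat must solve the dense normal
        equations (X_a' X_a)^{-1} X_a' d on the printed design."""
        net = hypothetical_network(effects=TABLE1_D)
        comps = build_combination(net.treatments, "+", inactive="Placebo")
        fit = fit_cnma(net, comps)
        np.testing.assert_array_equal(fit.Xa, TABLE1_XA)
        beta_oracle = np.linalg.solve(TABLE1_XA.T @ TABLE1_XA, TABLE1_XA.T @ TABLE1_D)
        np.testing.assert_allclose(fit.beta_hat, beta_oracle, atol=1e-10)
        np.testing.assert_allclose(fit.delta_hat, TABLE1_XA @ beta_oracle, atol=1e-10)

    def test_theta_and_delta_identities(self):
        net = hypothetical_network(effects=TABLE1_D)
        comps = build_combination(net.treatments, "+", inactive="Placebo")
        fit = fit_cnma(net, comps)
        np.testing.assert_allclose(fit.theta_hat, fit.C @ fit.beta_hat, atol=1e-14)
        np.testing.assert_allclose(fit.delta_hat, fit.B @ fit.theta_hat, atol=1e-12)

    def test_saturated_components_reproduce_standard_nma(self):
        """When each treatment is its own component (C square, full rank)
        the CNMA model is the standard NMA."""
        net = Network(
            [
                Contrast("s1", "A", "B", 1.0, 1.0),
                Contrast("s2", "A", "C", 0.4, 0.8),
                Contrast("s3", "B", "C", 0.2, 1.2),
                Contrast("s4", "A", "B", 0.6, 0.9),
            ]
        )
        comps = build_combination(net.treatments, separator="/")  # no splitting
        cfit = fit_cnma(net, comps, allow_rank_deficient=True)
        nfit = fit_nma(net)
        assert cfit.Q == pytest.approx(nfit.Q, abs=1e-12)
        np.testing.assert_allclose(cfit.delta_hat, nfit.delta_hat, atol=1e-10)

    def test_consistent_additive_data_fit_perfectly(self):
        beta = np.array([1.0, 0.5, -0.2])
        net = hypothetical_network(effects=TABLE1_XA @ beta)
        comps = build_combination(net.treatments, "+", inactive="Placebo")
        fit = fit_cnma(net, comps)
        np.testing.assert_allclose(fit.beta_hat, beta, atol=1e-12)
        assert fit.Q == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficient_design_rejected_with_names(self):
        # only A+B vs Placebo studied: A and B not separable
        net = Network(
            [
                Contrast("s1", "A+B", "Placebo", 1.0, 1.0),
                Contrast("s2", "A+B", "Placebo", 0.8, 1.0),
            ]
        )
        comps = build_combination(net.treatments, "+", inactive="Placebo")
        with pytest.raises(IdentificationError) as exc:
            fit_cnma(net, comps)
        assert set(exc.value.non_identified) == {"A", "B"}

    def test_rank_deficient_allowed_on_request(self):
        net = Network(
            [
                Contrast("s1", "A+B", "Placebo", 1.0, 1.0),
                Contrast("s2", "A+B", "Placebo", 0.8, 1.0),
            ]
        )
        comps = build_combination(net.treatments, "+", inactive="Placebo")
        fit = fit_cnma(net, comps, allow_rank_deficient=True)
        assert fit.rank == 1
        # the sum A+B is estimable and equals the pooled effect
        assert fit.beta_hat.sum() == pytest.approx(0.9)

    def test_multiplicative_or_identity_for_combinations(self):
        net = hypothetical_network(effects=TABLE1_D, se=[0.9, 1.1, 0.8, 1.2, 1.0, 0.7])
        comps = build_combination(net.treatments, "+", inactive="Placebo")
        fit = fit_cnma(net, comps, effects_model="random")
        theta = dict(zip(net.treatments, fit.theta_hat))
        beta = dict(zip(comps.components, fit.beta_hat))
        assert np.exp(theta["A+B"]) == pytest.approx(
            np.exp(beta["A"]) * np.exp(beta["B"]), rel=1e-12
        )
        assert np.exp(theta["A+B+C"]) == pytest.approx(
            np.exp(beta["A"]) * np.exp(beta["B"]) * np.exp(beta["C"]), rel=1e-12
        )


class TestQCnma:
    def test_df_accounts_for_rank(self):
        net = hypothetical_network(effects=TABLE1_D)
        comps = build_combination(net.treatments, "+", inactive="Placebo")
        fit = fit_cnma(net, comps)
        Q_a, df_a, p = q_cnma(net, fit)
        # two-arm-only network: df_a = k - r = 6 - 3
        assert df_a == 3
        assert Q_a == pytest.approx(fit.Q)
        assert Q_a >= fit_nma(net).Q - 1e-12


class TestAdditivityTest:
    def test_pythagorean_decomposition(self):
        net = hypothetical_network(effects=TABLE1_D)
        comps = build_combination(net.treatments, "+", inactive="Placebo")
        std, add = fit_nma(net), fit_cnma(net, comps)
        mc = additivity_test(std, add)
        diff = add.delta_hat_common - std.delta_hat_common
        qf = float(diff @ (std.w_common * diff))
        assert mc.Q_diff == pytest.approx(add.Q - std.Q, abs=1e-10)
        assert mc.Q_diff == pytest.approx(qf, abs=1e-10)
        assert mc.df_diff == (net.n - 1) - add.rank  # 4 - 3

    def test_identical_designs_give_zero(self):
        net = hypothetical_network(effects=TABLE1_D)
        comps = build_combination(net.treatments, separator="/")  # saturated
        std, sat = fit_nma(net), fit_cnma(net, comps, allow_rank_deficient=True)
        mc = additivity_test(std, sat)
        assert mc.Q_diff == pytest.approx(0.0, abs=1e-10)
        assert mc.df_diff == 0

    def test_weight_mismatch_rejected(self):
        net = hypothetical_network(effects=TABLE1_D)
        other = hypothetical_network(effects=TABLE1_D, se=[2.0] * 6)
        comps = build_combination(net.treatments, "+", inactive="Placebo")
        with pytest.raises(UsageError, match="weights"):
            additivity_test(fit_nma(net), fit_cnma(other, comps))

    def test_random_weight_variant_runs_on_heterogeneous_data(self):
        rng = np.random.default_rng(7)
        net = hypothetical_network(effects=rng.normal(0, 1.5, 6))
        comps = build_combination(net.treatments, "+", inactive="Placebo")
        std = fit_nma(net, "random")
        add = fit_cnma(net, comps, "random")
        mc = additivity_test(std, add, weights="random")
        assert mc.weights == "random"
        assert mc.Q_diff >= 0 and mc.df_diff == 1


class TestCompareNested:
    def _fits(self):
        rng = np.random.default_rng(3)
        net = hypothetical_network(effects=rng.normal(0.5, 1.0, 6))
        comps = build_combination(net.treatments, "+", inactive="Placebo")
        cint = add_interactions(comps, [("A", "B")])
        return net, fit_nma(net), fit_cnma(net, comps), fit_cnma(net, cint)

    def test_interaction_vs_additive(self):
        net, std, add, inter = self._fits()
        mc = compare_nested(inter, add)
        assert mc.Q_diff == pytest.approx(add.Q - inter.Q, abs=1e-10)
        assert mc.df_diff == 1

    def test_model_vs_itself_is_null(self):
        net, std, add, inter = self._fits()
        mc = compare_nested(add, add)
        assert (mc.Q_diff, mc.df_diff) == (0.0, 0)

    def test_q_differences_telescope(self):
        net, std, add, inter = self._fits()
        q_add_int = compare_nested(inter, add).Q_diff
        q_int_std = additivity_test(std, inter).Q_diff
        q_add_std = additivity_test(std, add).Q_diff
        assert q_add_int + q_int_std == pytest.approx(q_add_std, abs=1e-10)

    def test_non_nested_rejected(self):
        net, std, add, inter = self._fits()
        with pytest.raises(UsageError, match="nested"):
            compare_nested(add, inter)  # additive is not richer than interaction
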