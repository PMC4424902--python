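"""Hierarchical model: closed-form oracles, limits, and brute-force equivalence."""

import numpy as np
import pytest
from scipy.special import expit

import hiervar as hv
from hiervar.model import (
    PenalizedLogisticRegression,
    build_second_stage,
    estimate_tau2,
    fit_first_stage,
    fit_second_stage,
    rank_variants,
    shrink,
)


def _two_by_two_design():
    # carriers: 20 cases / 10 controls; non-carriers: 80 cases / 90 controls
    X = np.array([[1.0]] * 30 + [[0.0]] * 170)
    y = np.array([1] * 20 + [0] * 10 + [1] * 80 + [0] * 90, dtype=float)
    return X, y


class TestPenalizedLogistic:
    def test_two_by_two_closed_form(self):
        """Unpenalized single-variant fit equals the 2x2 log odds ratio."""
        X, y = _two_by_two_design()
        est = PenalizedLogisticRegression(penalty="none").fit(X, y)
        assert est.coef_[0] == pytest.approx(np.log((20 * 90) / (10 * 80)), abs=1e-6)

    def test_firth_finite_under_complete_separation(self):
        X = np.array([[1.0]] * 5 + [[0.0]] * 95)
        y = np.array([1] * 5 + [1] * 45 + [0] * 50, dtype=float)  # carriers all cases
        est = PenalizedLogisticRegression(penalty="firth").fit(X, y)
        assert np.isfinite(est.coef_[0])

    def test_firth_shrinks_separated_estimate(self):
        """The Jeffreys penalty keeps the separated coefficient moderate."""
        X = np.array([[1.0]] * 5 + [[0.0]] * 95)
        y = np.array([1] * 5 + [1] * 45 + [0] * 50, dtype=float)
        firth = PenalizedLogisticRegression(penalty="firth").fit(X, y)
        assert 0 < firth.coef_[0] < 5

    def test_wald_coverage_at_known_odds_ratio(self):
        """beta_hat within 2 SE of log(2) in >= 93% of 200 simulations."""
        rng = np.random.default_rng(2024)
        n, beta0, beta1 = 2000, -0.5, np.log(2)
        hits = 0
        for _ in range(200):
            x = (rng.random(n) < 0.3).astype(float)
            p = expit(beta0 + beta1 * x)
            y = (rng.random(n) < p).astype(float)
            est = PenalizedLogisticRegression(penalty="none").fit(x[:, None], y)
            se = np.sqrt(est.cov_params_[1, 1])
            hits += abs(est.coef_[0] - beta1) <= 2 * se
        assert hits / 200 >= 0.93

    def test_ridge_leaves_intercept_unpenalized(self):
        X, y = _two_by_two_design()
        lam = 1e6
        est = PenalizedLogisticRegression(penalty="ridge", penalty_strength=lam).fit(X, y)
        # variant coefficient crushed, intercept free to match marginal rate
        assert abs(est.coef_[0]) < 1e-3
        assert est.intercept_ == pytest.approx(np.log(100 / 100), abs=0.05)


class TestFirstStage:
    def test_duplicate_carrier_columns_aliased(self, small_replicate):
        geno, ann, truth, phen = small_replicate
        dup = hv.GenotypeMatrix(
            np.column_stack([geno.dosages, geno.dosages[:, 0]]),
            list(geno.sample_ids),
            list(geno.variant_ids) + ["dup:1:A:G"],
        )
        labels = hv.PhenotypeTable(list(dup.sample_ids), case_status=phen.case_status)
        fit = fit_first_stage(dup, labels, penalty="firth")
        assert fit.aliased.get("dup:1:A:G", None) == geno.variant_ids[0]
        j = list(dup.variant_ids).index(geno.variant_ids[0])
        assert fit.beta_hat[-1] == fit.beta_hat[j]

    def test_per_variant_mode_gives_diagonal_covariance(self, small_replicate):
        geno, _, _, phen = small_replicate
        labels = hv.PhenotypeTable(list(geno.sample_ids), case_status=phen.case_status)
        fit = fit_first_stage(geno, labels, penalty="firth", per_variant=True)
        off = fit.V - np.diag(np.diag(fit.V))
        assert np.all(off == 0)
        assert np.all(np.isfinite(fit.beta_hat))


class TestSecondStageDesign:
    def test_standardization_contract(self):
        d = build_second_stage(np.array([10.0, 20.0, 30.0]))
        col = d.Z[:, 1]
        assert col.mean() == pytest.approx(0, abs=1e-12)
        assert col.std() == pytest.approx(1, abs=1e-12)
        assert col[0] < col[1] < col[2]

    def test_raw_mode(self):
        s = np.array([3.0, 1.0, 4.0])
        d = build_second_stage(s, standardize=False)
        np.testing.assert_array_equal(d.Z[:, 1], s)

    def test_single_variant_errors(self):
        with pytest.raises(ValueError, match="single score"):
            build_second_stage(np.array([5.0]))

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero score variance"):
            build_second_stage(np.full(4, 2.0))


class TestTau2:
    def test_exact_fit_gives_zero(self):
        Z = np.column_stack([np.ones(4), np.arange(4.0)])
        beta = Z @ np.array([0.5, 2.0])
        assert estimate_tau2(beta, np.zeros((4, 4)) + 1e-12 * np.eye(4), Z) == 0.0

    def test_three_variant_hand_calculation(self):
        """Intercept-only toy: residuals [-1,-1,2], tr(MVM)=2, tr(M)=2."""
        Z = np.ones((3, 1))
        beta = np.array([0.0, 0.0, 3.0])
        tau2 = estimate_tau2(beta, np.eye(3), Z)
        assert tau2 == pytest.approx((6.0 - 2.0) / 2.0)

    def test_negative_raw_estimate_floored(self):
        Z = np.ones((3, 1))
        beta = np.array([0.01, -0.01, 0.0])
        assert estimate_tau2(beta, np.eye(3), Z) == 0.0

    def test_too_few_variants_errors(self):
        Z = np.column_stack([np.ones(2), np.arange(2.0)])
        with pytest.raises(ValueError, match="fixed-tau2"):
            estimate_tau2(np.zeros(2), np.eye(2), Z)


class TestSecondStageGls:
    def test_identity_reduces_to_mean(self):
        beta = np.array([1.0, 2.0, 6.0])
        gamma, cov = fit_second_stage(beta, np.eye(3), np.ones((3, 1)), 0.0)
        assert gamma[0] == pytest.approx(3.0)
        assert cov[0, 0] == pytest.approx(1 / 3)

    def test_scale_invariance(self):
        """Scaling V + tau2 I by any c > 0 leaves gamma_hat unchanged."""
        rng = np.random.default_rng(1)
        beta = rng.standard_normal(5)
        V = np.diag(rng.uniform(0.5, 2.0, 5))
        Z = np.column_stack([np.ones(5), rng.standard_normal(5)])
        g1, _ = fit_second_stage(beta, V, Z, 1.0)
        g2, _ = fit_second_stage(beta, 7.0 * V, Z, 7.0)
        np.testing.assert_allclose(g2, g1, rtol=1e-10)

    def test_weighted_normal_equations_oracle(self):
        """Direct solve of the weighted normal equations on a 3-variant toy."""
        beta = np.array([0.2, -0.1, 0.9])
        V = np.diag([1.0, 4.0, 9.0])
        s = np.array([1.0, 2.0, 5.0])
        Z = np.column_stack([np.ones(3), s])
        tau2 = 0.5
        gamma, cov = fit_second_stage(beta, V, Z, tau2)
        Wi = np.diag(1.0 / (np.diag(V) + tau2))
        A = Z.T @ Wi @ Z
        expected = np.linalg.solve(A, Z.T @ Wi @ beta)
        np.testing.assert_allclose(gamma, expected, atol=1e-12)
        np.testing.assert_allclose(cov, np.linalg.inv(A), atol=1e-12)


class TestShrink:
    def _toy(self):
        rng = np.random.default_rng(3)
        m = 4
        beta = rng.standard_normal(m)
        V = np.diag(rng.uniform(0.5, 2.0, m))
        Z = np.column_stack([np.ones(m), rng.standard_normal(m)])
        return beta, V, Z

    def test_zero_tau2_full_shrinkage_to_prediction(self):
        beta, V, Z = self._toy()
        gamma, cov = fit_second_stage(beta, V, Z, 0.0)
        fit = shrink(beta, V, Z, gamma, cov, 0.0)
        np.testing.assert_allclose(fit.beta_tilde, Z @ gamma, atol=1e-12)

    def test_huge_tau2_no_shrinkage(self):
        beta, V, Z = self._toy()
        tau2 = 1e6
        gamma, cov = fit_second_stage(beta, V, Z, tau2)
        fit = shrink(beta, V, Z, gamma, cov, tau2)
        np.testing.assert_allclose(fit.beta_tilde, beta, rtol=1e-3)

    def test_scalar_closed_form(self):
        """beta_hat=2, prediction 0, V=1, tau2=1 -> B=1/2 -> beta_tilde=1."""
        fit = shrink(
            np.array([2.0]), np.eye(1), np.ones((1, 1)),
            np.array([0.0]), np.eye(1) * 0.25, 1.0,
        )
        assert fit.beta_tilde[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_interpolation_with_diagonal_v(self, seed):
        """Each shrunken estimate lies between beta_hat and the prediction."""
        rng = np.random.default_rng(seed)
        m = 8
        beta = rng.standard_normal(m) * 2
        V = np.diag(rng.uniform(0.2, 3.0, m))
        Z = np.column_stack([np.ones(m), rng.standard_normal(m)])
        tau2 = rng.uniform(0.1, 2.0)
        gamma, cov = fit_second_stage(beta, V, Z, tau2)
        fit = shrink(beta, V, Z, gamma, cov, tau2, diag_v=True)
        pred = Z @ gamma
        lo = np.minimum(beta, pred) - 1e-12
        hi = np.maximum(beta, pred) + 1e-12
        assert np.all(fit.beta_tilde >= lo) and np.all(fit.beta_tilde <= hi)

    def test_sign_of_z_matches_beta_tilde(self):
        beta, V, Z = self._toy()
        gamma, cov = fit_second_stage(beta, V, Z, 0.7)
        fit = shrink(beta, V, Z, gamma, cov, 0.7)
        np.testing.assert_array_equal(np.sign(fit.z), np.sign(fit.beta_tilde))


class TestBruteForceEquivalence:
    def test_small_problem_matches_direct_implementation(self):
        """gamma, tau2, beta_tilde, z agree with explicit matrix arithmetic."""
        rng = np.random.default_rng(12)
        m = 5
        beta = rng.standard_normal(m)
        V = np.diag(rng.uniform(0.5, 1.5, m))
        s = rng.uniform(0, 30, m)
        Z = np.column_stack([np.ones(m), (s - s.mean()) / s.std()])

        # independent brute force: explicit construction, direct solves
        P = np.linalg.inv(Z.T @ Z) @ Z.T
        M = np.eye(m) - Z @ P
        r = M @ beta
        tau2_bf = max(0.0, (r @ r - np.trace(M @ V @ M)) / np.trace(M))
        W = V + tau2_bf * np.eye(m)
        Winv = np.linalg.inv(W)
        cov_bf = np.linalg.inv(Z.T @ Winv @ Z)
        gamma_bf = cov_bf @ Z.T @ Winv @ beta
        B = tau2_bf * np.linalg.inv(tau2_bf * np.eye(m) + V)
        bt_bf = Z @ gamma_bf + B @ (beta - Z @ gamma_bf)
        IB = np.eye(m) - B
        var_bf = B @ V @ B.T + IB @ Z @ cov_bf @ Z.T @ IB.T
        z_bf = bt_bf / np.sqrt(np.diag(var_bf))

        tau2 = estimate_tau2(beta, V, Z)
        gamma, cov = fit_second_stage(beta, V, Z, tau2)
        fit = shrink(beta, V, Z, gamma, cov, tau2)
        assert tau2 == pytest.approx(tau2_bf, abs=1e-10)
        np.testing.assert_allclose(gamma, gamma_bf, atol=1e-10)
        np.testing.assert_allclose(fit.beta_tilde, bt_bf, atol=1e-10)
        np.testing.assert_allclose(fit.z, z_bf, atol=1e-10)


class TestRanking:
    def test_sorted_by_z_descending(self):
        fit = shrink(
            np.array([0.5, 2.0, -1.0]), np.eye(3),
            np.column_stack([np.ones(3), [-1.0, 0.0, 1.0]]),
            np.array([0.0, 0.0]), np.eye(2) * 0.1, 1e6,
        )
        ranked = rank_variants(fit)
        assert [vid for vid, _ in ranked] == ["v1", "v0", "v2"]

    def test_ties_broken_lexicographically(self):
        fit = hv.HierarchicalFit(
            ["b", "a", "c"], np.zeros(3), np.zeros(2), np.eye(2), 1.0,
            np.ones(3), np.ones(3), np.ones(3),
        )
        assert [vid for vid, _ in rank_variants(fit)] == ["a", "b", "c"]

    def test_content_preserved(self, small_replicate):
        geno, ann, truth, phen = small_replicate
        est = hv.HierarchicalShrinkageRanker().fit(
            geno.dosages, phen.case_status,
            scores=ann.scores, variant_ids=list(geno.variant_ids),
        )
        ranked = est.rank()
        assert sorted(z for _, z in ranked) == sorted(est.z_.tolist())


class TestEstimatorApi:
    def test_sklearn_clone_and_params(self, small_replicate):
        from sklearn.base import clone

        est = hv.HierarchicalShrinkageRanker(penalty="ridge", tau2=0.5)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fitted_attributes(self, small_replicate):
        geno, ann, truth, phen = small_replicate
        est = hv.HierarchicalShrinkageRanker(penalty="ridge").fit(
            geno.dosages, phen.case_status,
            scores=ann.scores, variant_ids=list(geno.variant_ids),
        )
        m = geno.n_variants
        assert est.z_.shape == (m,)
        assert est.beta_tilde_.shape == (m,)
        assert est.V_.shape == (m, m)
        assert est.gamma_.shape == (2,)
        # raw-scale slope consistent with standardized slope
        assert est.gamma_raw_[1] == pytest.approx(
            est.gamma_[1] / est.design_.score_sd
        )

    def test_confounder_with_null_effect_is_harmless(self, small_replicate):
        geno, ann, truth, phen = small_replicate
        rng = np.random.default_rng(6)
        conf = rng.standard_normal(geno.n_individuals)
        base = hv.HierarchicalShrinkageRanker(penalty="ridge").fit(
            geno.dosages, phen.case_status,
            scores=ann.scores, variant_ids=list(geno.variant_ids),
        )
        with_conf = hv.HierarchicalShrinkageRanker(penalty="ridge").fit(
            geno.dosages, phen.case_status, scores=ann.scores,
            confounders=conf, variant_ids=list(geno.variant_ids),
        )
        # a null confounder barely perturbs the ranking
        rho = np.corrcoef(base.z_, with_conf.z_)[0, 1]
        assert rho > 0.95

    def test_scores_required(self, small_replicate):
        geno, _, _, phen = small_replicate
        with pytest.raises(ValueError, match="scores"):
            hv.HierarchicalShrinkageRanker().fit(geno.dosages, phen.case_status)
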