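"""Mediation decomposition: DE/IE algebra, draws-based inference, recovery."""

import numpy as np
import pandas as pd
import pytest

import methylaging as ma
from methylaging.lmm import fit_random_intercept
from methylaging.mediation import MediationCoefficients

from conftest import balanced_longitudinal

CONTRAST = ma.AgeContrast(2.0, 16.0)


def simulate_mediation(rng, n_subjects, alpha=0.02, beta_m=0.5,
                       beta_de=0.005, noise_m=0.1, noise_y=0.05,
                       subj_sd_m=0.1, subj_sd_y=0.03):
    """One CpG's (y, mediator) data with known mediation structure."""
    age, subj = balanced_longitudinal(n_subjects)
    n = age.size
    m = (alpha * age + subj_sd_m * rng.normal(size=n_subjects)[subj]
         + noise_m * rng.normal(size=n))
    y = (0.4 + beta_de * age + beta_m * m
         + subj_sd_y * rng.normal(size=n_subjects)[subj]
         + noise_y * rng.normal(size=n))
    return y, m, age, subj


class TestDecompose:
    def test_hand_arithmetic_product_formula(self):
        coeffs = MediationCoefficients(
            alpha=0.02, var_alpha=0.0, beta_de=0.005, beta_m=0.5,
            cov_outcome=np.zeros((2, 2)), converged=True)
        eff = ma.decompose_effects(coeffs, CONTRAST)
        assert eff["IE"] == pytest.approx(0.14)
        assert eff["DE"] == pytest.approx(0.07)
        assert eff["TE"] == pytest.approx(0.21)
        assert eff["prop_mediated"] == pytest.approx(2 / 3)

    def test_no_mediator_effect_means_te_equals_de(self):
        coeffs = MediationCoefficients(
            alpha=0.02, var_alpha=0.0, beta_de=0.005, beta_m=0.0,
            cov_outcome=np.zeros((2, 2)), converged=True)
        eff = ma.decompose_effects(coeffs, CONTRAST)
        assert eff["IE"] == 0.0
        assert eff["TE"] == eff["DE"]
        assert eff["prop_mediated"] == 0.0

    def test_opposed_paths_give_negative_proportion(self):
        """IE opposing DE yields a proportion mediated below zero."""
        coeffs = MediationCoefficients(
            alpha=-0.02, var_alpha=0.0, beta_de=0.01, beta_m=0.3,
            cov_outcome=np.zeros((2, 2)), converged=True)
        eff = ma.decompose_effects(coeffs, CONTRAST)
        assert eff["IE"] < 0 < eff["TE"]
        assert eff["prop_mediated"] < 0

    def test_tiny_te_leaves_proportion_undefined(self):
        coeffs = MediationCoefficients(
            alpha=0.0, var_alpha=0.0, beta_de=0.0, beta_m=0.0,
            cov_outcome=np.zeros((2, 2)), converged=True)
        eff = ma.decompose_effects(coeffs, CONTRAST)
        assert np.isnan(eff["prop_mediated"])

    def test_proportion_invariant_to_contrast_length(self):
        coeffs = MediationCoefficients(
            alpha=0.02, var_alpha=0.0, beta_de=0.005, beta_m=0.5,
            cov_outcome=np.zeros((2, 2)), converged=True)
        p1 = ma.decompose_effects(coeffs, ma.AgeContrast(2, 10))
        p2 = ma.decompose_effects(coeffs, ma.AgeContrast(2, 16))
        assert p1["prop_mediated"] == pytest.approx(p2["prop_mediated"])


class TestFitModels:
    def test_noiseless_data_matches_ols_oracle(self):
        age, subj = balanced_longitudinal(8)
        m = 0.1 + 0.02 * age + 0.001 * np.arange(24)
        y = 0.2 + 0.004 * age + 0.5 * m + 0.0002 * np.arange(24) ** 1.5
        coeffs = ma.fit_mediation_models(y, m, age, subj,
                                         random_intercept=False)
        X = np.c_[np.ones(24), age, m]
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        Xa = np.c_[np.ones(24), age]
        ols_a = np.linalg.lstsq(Xa, m, rcond=None)[0]
        assert coeffs.beta_de == pytest.approx(ols[1], abs=1e-8)
        assert coeffs.beta_m == pytest.approx(ols[2], abs=1e-8)
        assert coeffs.alpha == pytest.approx(ols_a[1], abs=1e-8)

    def test_broken_first_path(self):
        """Mediator independent of age: alpha and IE near zero."""
        rng = np.random.default_rng(11)
        y, m, age, subj = simulate_mediation(rng, 150, alpha=0.0)
        coeffs = ma.fit_mediation_models(y, m, age, subj)
        eff = ma.decompose_effects(coeffs, CONTRAST)
        assert abs(coeffs.alpha) < 0.005
        assert abs(eff["IE"]) < 0.05

    def test_broken_second_path(self):
        """Outcome ignores the mediator: IE ~ 0 and DE ~ TE."""
        rng = np.random.default_rng(12)
        y, m, age, subj = simulate_mediation(rng, 150, beta_m=0.0)
        coeffs = ma.fit_mediation_models(y, m, age, subj)
        eff = ma.decompose_effects(coeffs, CONTRAST)
        te = fit_random_intercept(
            y, np.c_[np.ones_like(age), age], subj).beta[1] * CONTRAST.delta
        assert abs(eff["IE"]) < 0.02
        assert eff["DE"] == pytest.approx(te, abs=0.02)

    def test_te_identity_with_separately_fitted_total_effect(self):
        """DE + IE equals the separate TE fit exactly on balanced data.

        On complete balanced data the mediator-model residual is
        orthogonal to (1, age) under every compound-symmetric weighting,
        so the product-of-coefficients TE matches the directly fitted
        total-effect slope times the contrast to well below 1e-6.
        """
        rng = np.random.default_rng(13)
        for _ in range(10):
            y, m, age, subj = simulate_mediation(rng, 19)
            coeffs = ma.fit_mediation_models(y, m, age, subj)
            eff = ma.decompose_effects(coeffs, CONTRAST)
            te_slope = fit_random_intercept(
                y, np.c_[np.ones_like(age), age], subj).beta[1]
            assert eff["TE"] == pytest.approx(te_slope * CONTRAST.delta,
                                              abs=1e-6)

    def test_ie_invariant_to_mediator_sign(self):
        """Flipping the PC1 sign convention flips alpha and beta_m only."""
        rng = np.random.default_rng(14)
        y, m, age, subj = simulate_mediation(rng, 50)
        a = ma.decompose_effects(
            ma.fit_mediation_models(y, m, age, subj), CONTRAST)
        b = ma.decompose_effects(
            ma.fit_mediation_models(y, -m, age, subj), CONTRAST)
        assert a["IE"] == pytest.approx(b["IE"], abs=1e-9)
        assert a["DE"] == pytest.approx(b["DE"], abs=1e-9)


class TestQuasiBayesian:
    def test_point_mass_limit(self):
        coeffs = MediationCoefficients(
            alpha=0.02, var_alpha=0.0, beta_de=0.005, beta_m=0.5,
            cov_outcome=np.zeros((2, 2)), converged=True)
        inf = ma.quasi_bayesian_inference(coeffs, CONTRAST, n_draws=999,
                                          seed=0)
        floor = 2.0 / 1000.0
        for eff in ("DE", "IE", "TE"):
            assert inf[f"p_{eff}"] == pytest.approx(floor)
            lo, hi = inf[f"ci_{eff}"]
            assert hi - lo == pytest.approx(0.0, abs=1e-12)
        null = MediationCoefficients(
            alpha=0.0, var_alpha=0.0, beta_de=0.0, beta_m=0.0,
            cov_outcome=np.zeros((2, 2)), converged=True)
        assert ma.quasi_bayesian_inference(null, CONTRAST,
                                           seed=0)["p_TE"] == 1.0

    def test_deterministic_under_seed(self):
        coeffs = MediationCoefficients(
            alpha=0.02, var_alpha=1e-5, beta_de=0.005, beta_m=0.5,
            cov_outcome=np.array([[4e-6, 1e-6], [1e-6, 9e-6]]),
            converged=True)
        a = ma.quasi_bayesian_inference(coeffs, CONTRAST, seed=42)
        b = ma.quasi_bayesian_inference(coeffs, CONTRAST, seed=42)
        assert a == b

    def test_non_positive_definite_covariance_flagged(self):
        coeffs = MediationCoefficients(
            alpha=0.02, var_alpha=1e-5, beta_de=0.005, beta_m=0.5,
            cov_outcome=np.array([[1e-6, 5e-6], [5e-6, 1e-6]]),
            converged=True)
        with pytest.raises(ValueError, match="positive-definite"):
            ma.quasi_bayesian_inference(coeffs, CONTRAST, seed=0)

    def test_ci_coverage_of_true_effects(self):
        """95% draw-based CIs cover the true DE and IE at nominal rate."""
        rng = np.random.default_rng(15)
        alpha, beta_m, beta_de = 0.02, 0.5, 0.005
        true_de = beta_de * CONTRAST.delta
        true_ie = alpha * beta_m * CONTRAST.delta
        n_rep, cover_de, cover_ie = 500, 0, 0
        for _ in range(n_rep):
            y, m, age, subj = simulate_mediation(
                rng, 100, alpha=alpha, beta_m=beta_m, beta_de=beta_de)
            coeffs = ma.fit_mediation_models(y, m, age, subj)
            inf = ma.quasi_bayesian_inference(
                coeffs, CONTRAST, n_draws=400,
                seed=int(rng.integers(2 ** 31)))
            lo, hi = inf["ci_DE"]
            cover_de += lo <= true_de <= hi
            lo, hi = inf["ci_IE"]
            cover_ie += lo <= true_ie <= hi
        se = np.sqrt(0.95 * 0.05 / n_rep)
        assert abs(cover_de / n_rep - 0.95) < 3 * se
        assert abs(cover_ie / n_rep - 0.95) < 3 * se


class TestRunMediationEwas:
    def test_empty_matrix_gives_empty_result(self, cohort, cohort_pc1):
        _, m, _ = cohort
        res = ma.run_mediation_ewas(m.subset_sites(np.array([], dtype=int)),
                                    cohort_pc1.scores)
        assert len(res) == 0

    def test_determinism_under_seed(self, cohort, cohort_pc1):
        _, m, _ = cohort
        sub = m.subset_sites(np.arange(10))
        a = ma.run_mediation_ewas(sub, cohort_pc1.scores, seed=5)
        b = ma.run_mediation_ewas(sub, cohort_pc1.scores, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_te_equals_de_plus_ie_pointwise(self, cohort, cohort_pc1):
        _, m, _ = cohort
        res = ma.run_mediation_ewas(m.subset_sites(np.arange(40)),
                                    cohort_pc1.scores, seed=1)
        ok = res["converged"]
        np.testing.assert_allclose(
            res.loc[ok, "TE"], res.loc[ok, "DE"] + res.loc[ok, "IE"],
            atol=1e-12)

    def test_missing_mediator_rejected(self, cohort, cohort_pc1):
        _, m, _ = cohort
        scores = cohort_pc1.scores.iloc[:-3]
        with pytest.raises(ValueError, match="PC1"):
            ma.run_mediation_ewas(m.subset_sites(np.arange(4)), scores)


class TestClassification:
    def test_explicit_counts(self):
        res = pd.DataFrame({"prop_mediated": [0.3, -0.1, 1.2]})
        tab = ma.classify_prop_mediated(res)
        assert tab.loc["partial", "count"] == 1
        assert tab.loc["inconsistent", "count"] == 1
        assert tab.loc["amplified", "count"] == 1

    def test_single_class_statistics(self):
        vals = [0.2, 0.4, 0.6]
        tab = ma.classify_prop_mediated(
            pd.DataFrame({"prop_mediated": vals}))
        assert tab.loc["partial", "count"] == 3
        assert tab.loc["partial", "mean"] == pytest.approx(np.mean(vals))
        assert tab.loc["partial", "min"] == 0.2
        assert tab.loc["partial", "max"] == 0.6
        assert tab.loc["inconsistent", "count"] == 0

    def test_recovers_planted_class_fractions(self):
        """Estimated proportion classes track the simulated mixture."""
        rng = np.random.default_rng(16)
        props = []
        for _ in range(120):
            opposed = rng.random() < 0.25
            alpha = -0.02 if opposed else 0.02
            y, m, age, subj = simulate_mediation(
                rng, 120, alpha=alpha, beta_m=0.4, beta_de=0.01,
                noise_y=0.02, subj_sd_y=0.01)
            coeffs = ma.fit_mediation_models(y, m, age, subj)
            props.append(ma.decompose_effects(
                coeffs, CONTRAST)["prop_mediated"])
        tab = ma.classify_prop_mediated(
            pd.DataFrame({"prop_mediated": props}))
        frac_inconsistent = tab.loc["inconsistent", "count"] / 120
        se = np.sqrt(0.25 * 0.75 / 120)
        assert abs(frac_inconsistent - 0.25) < 3.5 * se
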