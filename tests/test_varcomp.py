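"""AI-REML engine and heritability estimators.

Oracles: closed-form balanced one-way ANOVA estimators, direct numerical
maximization of the coded REML log-likelihood, and hand-computed
delta-method expressions.
"""

import numpy as np
import pytest
from scipy import optimize

from poolherit import (
    MixedModelSpec,
    RandomTerm,
    SimulationScenario,
    ValidationError,
    VarianceComponentFit,
    compute_grm,
    fit_family_gblup,
    heritabilities,
    heritability_se,
    incidence_matrix,
    reml_fit,
    reml_loglik,
    simulate_dataset,
    total_variance,
)


def random_psd(n, rng, jitter=0.05):
    A = rng.standard_normal((n, n))
    return A @ A.T / n + jitter * np.eye(n)


def one_way_data(q=20, r=5, sg2=2.0, se2=1.0, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(sg2), q)
    y = (np.repeat(g, r) + rng.normal(0, np.sqrt(se2), q * r)) + 5.0
    groups = np.repeat(np.arange(q), r)
    return y, groups


class TestAgainstClosedFormAnova:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_balanced_one_way(self, seed):
        q, r = 20, 5
        y, groups = one_way_data(q, r, seed=seed)
        ybar = y.mean()
        gm = y.reshape(q, r).mean(axis=1)
        msb = r * np.sum((gm - ybar) ** 2) / (q - 1)
        mse = np.sum((y.reshape(q, r) - gm[:, None]) ** 2) / (q * (r - 1))
        assert msb > mse   # interior optimum required for the closed form
        Z, _ = incidence_matrix(groups)
        spec = MixedModelSpec(
            y=y, X=np.ones((q * r, 1)), random_terms=[RandomTerm("group", Z)]
        )
        fit = reml_fit(spec)
        assert fit.estimates["residual"] == pytest.approx(mse, rel=1e-6)
        assert fit.estimates["group"] == pytest.approx((msb - mse) / r, rel=1e-6)


class TestAgainstNumericalOptimizer:
    @pytest.mark.parametrize("seed,two_terms", [(0, False), (1, False), (2, True)])
    def test_ai_reml_matches_direct_maximization(self, seed, two_terms):
        rng = np.random.default_rng(seed)
        n = 30
        G = random_psd(n, rng)
        Z = np.eye(n)
        rt = [RandomTerm("genomic", Z, G)]
        parts = [G]
        theta_true = [1.0, 1.0]
        if two_terms:
            fam = np.repeat(np.arange(n // 2), 2)
            Zf, _ = incidence_matrix(fam)
            rt.append(RandomTerm("family", Zf))
            parts.append(Zf @ Zf.T)
            theta_true = [1.0, 0.5, 1.0]
        L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
        y = L @ rng.standard_normal(n) + rng.standard_normal(n)
        if two_terms:
            y = y + np.repeat(rng.normal(0, 0.7, n // 2), 2)
        X = np.ones((n, 1))
        fit = reml_fit(MixedModelSpec(y=y, X=X, random_terms=rt))

        def neg(log_theta):
            return -reml_loglik(np.exp(log_theta), y, X, parts)

        res = optimize.minimize(
            neg, np.log(theta_true), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        assert fit.loglik >= -res.fun - 1e-4

    def test_boundary_component_estimated_near_zero(self):
        # data generated with zero genomic variance
        rng = np.random.default_rng(3)
        n = 40
        G = random_psd(n, rng)
        y = rng.standard_normal(n)
        fit = fit_family_gblup(y, np.arange(n), G)
        s2 = y.var()
        assert fit.estimates["genomic"] < 0.05 * s2
        # optimum dominates a small grid of alternative points
        lam, U = np.linalg.eigh(G)
        ystar, Xstar = U.T @ y, (U.T @ np.ones(n))[:, None]
        for tg in (0.1, 0.5, 1.0):
            ll = reml_loglik([tg, fit.estimates["residual"]], ystar, Xstar, [lam], diag=True)
            assert fit.loglik >= ll - 1e-8


class TestEnginesAgree:
    def test_spectral_path_equals_dense_fit(self):
        rng = np.random.default_rng(7)
        q = 30
        G = random_psd(q, rng)
        fam = np.repeat(np.arange(q), 2)
        g = np.linalg.cholesky(G + 1e-8 * np.eye(q)) @ rng.standard_normal(q)
        y = np.repeat(g, 2) + np.repeat(rng.normal(0, 0.7, q), 2) + rng.standard_normal(2 * q)
        fast = fit_family_gblup(y, fam, G)
        Z, _ = incidence_matrix(fam)
        spec = MixedModelSpec(
            y=y, X=np.ones((2 * q, 1)),
            random_terms=[RandomTerm("genomic", Z, G), RandomTerm("family", Z)],
        )
        dense = reml_fit(spec)
        assert fast.loglik == pytest.approx(dense.loglik, abs=1e-6)
        for name in ("genomic", "family", "residual"):
            assert fast.estimates[name] == pytest.approx(
                dense.estimates[name], rel=1e-4, abs=1e-8
            )

    def test_loglik_invariant_to_fixed_reparameterization(self):
        rng = np.random.default_rng(8)
        n = 24
        G = random_psd(n, rng)
        y = rng.standard_normal(n)
        X1 = np.ones((n, 1))
        X2 = np.hstack([X1, X1])   # over-parameterized: duplicated constant
        theta = [0.5, 1.2]
        assert reml_loglik(theta, y, X1, [G]) == pytest.approx(
            reml_loglik(theta, y, X2, [G]), abs=1e-10
        )

    def test_estimates_invariant_to_observation_order(self):
        y, groups = one_way_data(10, 3, seed=9)
        perm = np.random.default_rng(0).permutation(len(y))
        Z1, _ = incidence_matrix(groups)
        Z2, _ = incidence_matrix(groups[perm])
        f1 = reml_fit(MixedModelSpec(y=y, X=np.ones((len(y), 1)), random_terms=[RandomTerm("g", Z1)]))
        f2 = reml_fit(MixedModelSpec(y=y[perm], X=np.ones((len(y), 1)), random_terms=[RandomTerm("g", Z2)]))
        assert f1.estimates["g"] == pytest.approx(f2.estimates["g"], rel=1e-8)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)

    def test_objective_nondecreasing_over_iterations(self):
        y, groups = one_way_data(15, 4, seed=10)
        Z, _ = incidence_matrix(groups)
        fit = reml_fit(MixedModelSpec(y=y, X=np.ones((len(y), 1)), random_terms=[RandomTerm("g", Z)]))
        lls = [ll for _, ll in fit.history]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_family_term_rejected_for_single_replicate(self):
        rng = np.random.default_rng(11)
        G = random_psd(10, rng)
        with pytest.raises(ValidationError):
            fit_family_gblup(rng.standard_normal(10), np.arange(10), G, include_family=True)


class TestParameterRecovery:
    def test_gblup_recovers_truth_on_noiseless_genotypes(self):
        # true sigma2_g = 1 (standardized), sigma2_e = 3; estimates across
        # datasets should straddle the truth within Monte Carlo error
        h2 = []
        for seed in range(12):
            ds = simulate_dataset(
                SimulationScenario(
                    n_families=200, n_snps=400, n_qtl=400, depth="infinite", seed=seed
                )
            )
            grm = compute_grm(ds.true_pool_freqs)
            fam = np.arange(200)
            fit = fit_family_gblup(ds.phenotypes["value"].to_numpy(), fam, grm.G)
            h2.append(heritabilities(fit, grm.mean_diagonal).h2_G)
        mc_se = np.std(h2, ddof=1) / np.sqrt(len(h2))
        assert abs(np.mean(h2) - 0.25) < 3 * mc_se


def make_fit(names, theta, cov=None):
    k = len(names)
    return VarianceComponentFit(
        names=names,
        estimates=dict(zip(names, theta)),
        cov=np.zeros((k, k)) if cov is None else np.asarray(cov, float),
        loglik=0.0, n_iter=1, converged=True,
    )


class TestHeritabilityFormulas:
    def test_total_variance_substitution(self):
        fit = make_fit(["genomic", "family", "residual"], [1.0, 0.5, 2.5])
        assert total_variance(fit, 1.0) == pytest.approx(4.0)
        fit = make_fit(["residual"], [1.0])
        assert total_variance(fit, 1.0) == pytest.approx(1.0)
        fit = make_fit(["genomic", "parent_population", "residual"], [0.0, 0.1, 1.0])
        assert total_variance(fit, 1.0, ww_diag=2.0) == pytest.approx(1.2)
        with pytest.raises(ValidationError):
            total_variance(fit, -1.0)

    def test_heritabilities_at_unit_diagonal(self):
        fit = make_fit(["genomic", "family", "residual"], [1.0, 0.5, 2.5])
        est = heritabilities(fit, 1.0)
        assert est.h2_G == pytest.approx(0.25)
        assert est.H2 == pytest.approx(0.375)

    def test_diagonal_inflation_attenuates_narrow_sense(self):
        fit = make_fit(["genomic", "family", "residual"], [0.8, 0.5, 2.5])
        est = heritabilities(fit, 1.25)
        assert est.var_y == pytest.approx(4.0)
        assert est.h2_G == pytest.approx(0.20)
        assert est.H2 == pytest.approx(0.375)

    def test_pure_noise_gives_zero(self):
        fit = make_fit(["genomic", "family", "residual"], [0.0, 0.0, 2.0])
        est = heritabilities(fit, 1.0)
        assert est.h2_G == 0.0 and est.H2 == 0.0

    def test_ordering_invariant(self):
        fit = make_fit(
            ["genomic", "family", "parent_population", "residual"],
            [0.9, 0.3, 0.2, 2.0],
        )
        est = heritabilities(fit, 1.2)
        assert 0 <= est.h2_G <= est.h2_G_PP <= est.H2 <= 1


class TestDeltaMethodSE:
    def test_zero_covariance_gives_zero_se(self):
        fit = make_fit(["genomic", "residual"], [1.0, 3.0])
        se = heritability_se(fit, 1.0)
        assert all(v == 0.0 for v in se.values())

    def test_hand_computed_two_component_case(self):
        # h2 = sg/(sg+se); grad = (se, -sg)/(sg+se)^2; SE^2 = g'Cg
        sg, se_ = 1.0, 3.0
        C = np.array([[0.04, -0.01], [-0.01, 0.09]])
        fit = make_fit(["genomic", "residual"], [sg, se_], cov=C)
        grad = np.array([se_, -sg]) / (sg + se_) ** 2
        expected = float(np.sqrt(grad @ C @ grad))
        assert heritability_se(fit, 1.0)["h2_G"] == pytest.approx(expected)

    def test_scale_invariance_of_ratio_se(self):
        C = np.array([[0.04, -0.01], [-0.01, 0.09]])
        f1 = make_fit(["genomic", "residual"], [1.0, 3.0], cov=C)
        c = 7.3
        f2 = make_fit(["genomic", "residual"], [c * 1.0, c * 3.0], cov=c ** 2 * C)
        assert heritability_se(f1, 1.0)["h2_G"] == pytest.approx(
            heritability_se(f2, 1.0)["h2_G"]
        )
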