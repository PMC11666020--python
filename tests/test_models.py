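"""Kernel construction, Gibbs sampler, closed-form BLUP oracle, prediction."""

import numpy as np
import pandas as pd
import pytest

import phenogp as pg
from phenogp.kinship import Kinship
from phenogp.models import ChainParams, build_kernels, fit_gibbs, predict, solve_blup


def random_kinship(n, m, seed, ids=None):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, m))
    return Kinship(Z @ Z.T / m, ids or [f"G{i}" for i in range(n)], "genomic")


@pytest.fixture()
def toy_problem():
    n = 30
    K = random_kinship(n, 90, seed=0)
    idx = pd.DataFrame({"genotype": K.ids * 2, "env": ["A"] * n + ["B"] * n})
    rng = np.random.default_rng(1)
    y = rng.normal(size=2 * n) + 1.5
    mask = np.zeros(2 * n, bool)
    mask[rng.choice(2 * n, 10, replace=False)] = True
    return K, idx, y, mask


class TestBuildKernels:
    def test_mds_entries_match_explicit_kronecker(self):
        """Main and GxE kernels equal J (x) K and I (x) K restricted to the
        stacked index, checked entrywise on a 3-genotype x 2-environment toy."""
        K = random_kinship(3, 12, seed=2)
        idx = pd.DataFrame({"genotype": K.ids * 2, "env": ["E1"] * 3 + ["E2"] * 3})
        ks = build_kernels("MDs", "GP", grm=K, index=idx)
        labels = {lab: M for lab, M, _ in ks.kernels}
        assert set(labels) == {"g_main", "g_gxe"}
        J = np.ones((2, 2))
        I = np.eye(2)
        np.testing.assert_allclose(labels["g_main"], np.kron(J, K.matrix), atol=1e-12)
        np.testing.assert_allclose(labels["g_gxe"], np.kron(I, K.matrix), atol=1e-12)
        # families recorded
        fams = {lab: f for lab, _, f in ks.kernels}
        assert fams["g_main"].startswith("main") and fams["g_gxe"].startswith("gxe")

    def test_mm_single_environment_equals_sm(self):
        K = random_kinship(4, 20, seed=3)
        idx = pd.DataFrame({"genotype": K.ids, "env": "E1"})
        sm = build_kernels("SM", "GP", grm=K, index=idx)
        mm = build_kernels("MM", "GP", grm=K, index=idx)
        np.testing.assert_allclose(sm.kernels[0][1], mm.kernels[0][1], atol=1e-12)
        np.testing.assert_allclose(sm.X, mm.X)

    def test_kernel_count_gp_pp_mds_four_envs(self):
        n = 5
        K = random_kinship(n, 30, seed=4)
        hrms = {f"E{d}": random_kinship(n, 25, seed=10 + d) for d in range(1, 4)}
        idx = pd.DataFrame(
            {"genotype": K.ids * 4, "env": sum(([f"E{e}"] * n for e in range(1, 5)), [])}
        )
        ks = build_kernels("MDs", "GP+PP", grm=K, hrms=hrms, index=idx)
        # 1 genomic main + 1 genomic GxE + 3 phenomic mains + 3 phenomic GxE
        assert len(ks.kernels) == 2 + 2 * len(hrms)

    def test_sm_rejects_multiple_environments(self, toy_problem):
        K, idx, *_ = toy_problem
        with pytest.raises(ValueError):
            build_kernels("SM", "GP", grm=K, index=idx)

    def test_missing_inputs_rejected(self, toy_problem):
        K, idx, *_ = toy_problem
        with pytest.raises(ValueError):
            build_kernels("MM", "GP", grm=None, index=idx)
        with pytest.raises(ValueError):
            build_kernels("MM", "PP", hrms=None, index=idx)


class TestSolveBlup:
    def test_identity_kernel_is_ridge_shrinkage(self):
        n = 40
        ids = [f"G{i}" for i in range(n)]
        K = Kinship(np.eye(n), ids, "genomic")
        idx = pd.DataFrame({"genotype": ids, "env": "E"})
        ks = build_kernels("SM", "GP", grm=K, index=idx)
        rng = np.random.default_rng(5)
        y = rng.normal(size=n)
        mask = np.zeros(n, bool)
        lam = 2.0  # s2_g / s2_e
        sol = solve_blup(y, mask, ks, {"g_main": lam, "residual": 1.0})
        yc = y - y.mean()
        np.testing.assert_allclose(
            sol.effects["g_main"], yc * lam / (lam + 1), atol=1e-8
        )

    def test_unrelated_masked_genotype_predicted_at_fixed_part(self):
        n = 10
        ids = [f"G{i}" for i in range(n)]
        M = np.eye(n)
        M[-1, -1] = 1e-12  # final genotype unrelated to everyone, ~zero variance
        K = Kinship(M, ids, "genomic")
        idx = pd.DataFrame({"genotype": ids, "env": "E"})
        ks = build_kernels("SM", "GP", grm=K, index=idx)
        y = np.arange(n, dtype=float)
        mask = np.zeros(n, bool)
        mask[-1] = True
        sol = solve_blup(y, mask, ks, {"g_main": 3.0, "residual": 1.0})
        assert sol.fitted[-1] == pytest.approx(sol.beta[0], abs=1e-6)

    def test_matches_dense_gls_oracle(self, toy_problem):
        """Mixed-model-equation solution equals conditional-Gaussian (GLS)
        prediction from the explicit joint covariance."""
        K, idx, y, mask = toy_problem
        ks = build_kernels("MDs", "GP", grm=K, index=idx)
        var = {"g_main": 0.8, "g_gxe": 0.4, "residual": 0.6}
        sol = solve_blup(y, mask, ks, var)
        n = len(idx)
        V = var["residual"] * np.eye(n)
        C = np.zeros((n, n))
        for lab, M, _ in ks.kernels:
            V += var[lab] * M
            C += var[lab] * M
        obs = ~mask
        X = ks.X
        Vi = np.linalg.inv(V[np.ix_(obs, obs)])
        beta = np.linalg.solve(X[obs].T @ Vi @ X[obs], X[obs].T @ Vi @ y[obs])
        pred = X[mask] @ beta + C[np.ix_(mask, obs)] @ Vi @ (y[obs] - X[obs] @ beta)
        np.testing.assert_allclose(sol.fitted[mask], pred, atol=1e-8)

    def test_two_random_psd_kernels_against_gls(self):
        n = 30
        ids = [f"G{i}" for i in range(n)]
        K1 = random_kinship(n, 50, seed=8, ids=ids)
        K2 = random_kinship(n, 45, seed=9, ids=ids)
        idx = pd.DataFrame({"genotype": ids, "env": "E"})
        ks = build_kernels("SM", "GP+PP", grm=K1, hrms={"E": K2}, index=idx)
        rng = np.random.default_rng(10)
        y = rng.normal(size=n)
        mask = np.zeros(n, bool)
        mask[:6] = True
        var = {lab: v for (lab, _, _), v in zip(ks.kernels, (1.2, 0.7))}
        var["residual"] = 0.9
        sol = solve_blup(y, mask, ks, var)
        V = var["residual"] * np.eye(n)
        C = np.zeros((n, n))
        for lab, M, _ in ks.kernels:
            V += var[lab] * M
            C += var[lab] * M
        obs = ~mask
        Vi = np.linalg.inv(V[np.ix_(obs, obs)])
        X = ks.X
        beta = np.linalg.solve(X[obs].T @ Vi @ X[obs], X[obs].T @ Vi @ y[obs])
        pred = X[mask] @ beta + C[np.ix_(mask, obs)] @ Vi @ (y[obs] - X[obs] @ beta)
        np.testing.assert_allclose(sol.fitted[mask], pred, atol=1e-8)

    def test_nonpositive_variance_rejected(self, toy_problem):
        K, idx, y, mask = toy_problem
        ks = build_kernels("MDs", "GP", grm=K, index=idx)
        with pytest.raises(ValueError):
            solve_blup(y, mask, ks, {"g_main": 0.0, "g_gxe": 1.0, "residual": 1.0})


class TestGibbs:
    def test_deterministic_given_seed(self, toy_problem):
        K, idx, y, mask = toy_problem
        ks = build_kernels("MDs", "GP", grm=K, index=idx)
        chain = ChainParams(burn_in=100, n_iter=600, thin=5, seed=11)
        a = fit_gibbs(y, mask, ks, chain)
        b = fit_gibbs(y, mask, ks, chain)
        np.testing.assert_array_equal(a.fitted_mean, b.fitted_mean)
        assert a.variance_mean == b.variance_mean

    def test_retained_sample_count(self, toy_problem):
        K, idx, y, mask = toy_problem
        ks = build_kernels("MM", "GP", grm=K, index=idx)
        fit = fit_gibbs(y, mask, ks, ChainParams(burn_in=100, n_iter=600, thin=5, seed=1))
        assert fit.n_retained == 100

    def test_matches_blup_oracle_at_fixed_variances(self, toy_problem):
        K, idx, y, mask = toy_problem
        ks = build_kernels("MDs", "GP", grm=K, index=idx)
        var = {"g_main": 1.0, "g_gxe": 0.5, "residual": 1.0}
        sol = solve_blup(y, mask, ks, var)
        fit = fit_gibbs(y, mask, ks, ChainParams.fast(seed=5, fixed_variances=var))
        se = fit.prediction_mc_se()
        z = np.abs(fit.fitted_mean[mask] - sol.fitted[mask]) / se
        assert np.mean(z < 2) >= 0.9
        assert z.max() < 4

    def test_near_zero_genetic_variance_predicts_fixed_part(self):
        n = 25
        ids = [f"G{i}" for i in range(n)]
        K = random_kinship(n, 60, seed=12, ids=ids)
        idx = pd.DataFrame({"genotype": ids, "env": "E"})
        ks = build_kernels("SM", "GP", grm=K, index=idx)
        rng = np.random.default_rng(13)
        y = 4.0 + rng.normal(size=n)
        mask = np.zeros(n, bool)
        mask[:5] = True
        fit = fit_gibbs(y, mask, ks,
                        ChainParams.fast(seed=6, fixed_variances={"g_main": 1e-10, "residual": 1.0}))
        spread = np.ptp(fit.fitted_mean[mask])
        assert spread < 0.05
        assert fit.fitted_mean[mask].mean() == pytest.approx(fit.beta_mean[0], abs=0.05)

    def test_heritability_posterior_recovers_half(self):
        n = 500
        ids = [f"G{i}" for i in range(n)]
        K = Kinship(np.eye(n), ids, "genomic")
        idx = pd.DataFrame({"genotype": ids, "env": "E"})
        ks = build_kernels("SM", "GP", grm=K, index=idx)
        rng = np.random.default_rng(14)
        y = rng.normal(0, 1, n) + rng.normal(0, 1, n)
        fit = fit_gibbs(y, np.zeros(n, bool), ks, ChainParams.fast(seed=7))
        h2 = fit.variance_mean["g_main"] / (
            fit.variance_mean["g_main"] + fit.variance_mean["residual"]
        )
        assert abs(h2 - 0.5) < 0.15

    def test_all_masked_rejected(self, toy_problem):
        K, idx, y, _ = toy_problem
        ks = build_kernels("MDs", "GP", grm=K, index=idx)
        with pytest.raises(ValueError):
            fit_gibbs(y, np.ones(len(idx), bool), ks, ChainParams.fast(seed=1))

    def test_exchangeability_under_index_permutation(self, toy_problem):
        """Permuting the stacked index permutes predictions identically."""
        K, idx, y, mask = toy_problem
        ks = build_kernels("MDs", "GP", grm=K, index=idx)
        var = {"g_main": 1.0, "g_gxe": 0.5, "residual": 1.0}
        sol = solve_blup(y, mask, ks, var)
        perm = np.random.default_rng(15).permutation(len(idx))
        idx_p = idx.iloc[perm].reset_index(drop=True)
        ks_p = build_kernels("MDs", "GP", grm=K, index=idx_p)
        sol_p = solve_blup(y[perm], mask[perm], ks_p, var)
        np.testing.assert_allclose(sol_p.fitted, sol.fitted[perm], atol=1e-8)


class TestPredict:
    def test_observed_target_returns_fitted_value(self, toy_problem):
        K, idx, y, mask = toy_problem
        ks = build_kernels("MDs", "GP", grm=K, index=idx)
        fit = fit_gibbs(y, mask, ks, ChainParams.fast(seed=2))
        g, e = idx.iloc[0]["genotype"], idx.iloc[0]["env"]
        out = predict(fit, [(g, e)])
        assert out["predicted"].iloc[0] == pytest.approx(fit.fitted_mean[0])

    def test_empty_target_list(self, toy_problem):
        K, idx, y, mask = toy_problem
        ks = build_kernels("MDs", "GP", grm=K, index=idx)
        fit = fit_gibbs(y, mask, ks, ChainParams.fast(seed=2))
        assert len(predict(fit, [])) == 0

    def test_unknown_target_rejected(self, toy_problem):
        K, idx, y, mask = toy_problem
        ks = build_kernels("MDs", "GP", grm=K, index=idx)
        fit = fit_gibbs(y, mask, ks, ChainParams.fast(seed=2))
        with pytest.raises(KeyError):
            predict(fit, [("nope", "A")])

    def test_fully_masked_environment_ranked_by_main_effects(self):
        """With an all-masked environment under MM, predictions there are a
        monotone function of the main genomic effects."""
        n = 20
        K = random_kinship(n, 60, seed=16)
        idx = pd.DataFrame({"genotype": K.ids * 2, "env": ["A"] * n + ["B"] * n})
        rng = np.random.default_rng(17)
        y = rng.normal(size=2 * n)
        mask = np.zeros(2 * n, bool)
        mask[n:] = True
        ks = build_kernels("MM", "GP", grm=K, index=idx, observed=~mask)
        var = {"g_main": 1.0, "residual": 0.5}
        sol = solve_blup(y, mask, ks, var)
        pred_b = sol.fitted[n:]
        main = sol.effects["g_main"][n:]
        assert np.corrcoef(pred_b, main)[0, 1] > 0.9999
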