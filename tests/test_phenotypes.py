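"""Phenotype analysis: outlier rule, REML decomposition, H2, BLUEs, correlations."""

import numpy as np
import pandas as pd
import pytest

import phenogp as pg
from phenogp.phenotypes import VarianceComponents, design_harmonic_means, tukey_hinges
from phenogp.reml import fit_reml


def make_records(values, env="2015-HN", trait="t"):
    year, nitro = env.split("-")
    n = len(values)
    return pd.DataFrame(
        dict(
            genotype=[f"G{i}" for i in range(n)],
            year=int(year),
            nitro=nitro,
            env=env,
            rep=1,
            block=1,
            trait=trait,
            value=values,
        )
    )


class TestOutliers:
    def test_constant_vector_has_no_flags(self):
        rec = make_records([5.0] * 10)
        assert not pg.flag_outliers(rec).any()

    def test_single_extreme_value_flagged(self):
        # {1..9, 100}: hinges 3 and 8, fences [-4.5, 15.5] -> only 100 outside
        rec = make_records(list(range(1, 10)) + [100])
        flags = pg.flag_outliers(rec, coef=1.5)
        assert flags.sum() == 1
        assert flags.iloc[-1]

    def test_small_group_warns_and_skips(self):
        rec = make_records([1.0, 2.0, 50.0])
        with pytest.warns(UserWarning):
            flags = pg.flag_outliers(rec)
        assert not flags.any()

    def test_hinges_match_boxplot_convention(self):
        # fivenum hinges of 1..9 are 3 and 7 (medians of halves incl. median)
        lo, hi = tukey_hinges(np.arange(1, 10))
        assert (lo, hi) == (3.0, 7.0)


class TestRemlEngine:
    @pytest.mark.parametrize("a,r,sg,se,seed", [(25, 4, 2.0, 1.5, 0), (40, 3, 0.5, 2.0, 1)])
    def test_balanced_one_way_matches_anova(self, a, r, sg, se, seed):
        """On balanced one-way designs REML equals the expected-mean-squares
        closed form (when the estimate is interior)."""
        rng = np.random.default_rng(seed)
        y = np.repeat(rng.normal(0, np.sqrt(sg), a), r) + rng.normal(0, np.sqrt(se), a * r)
        res = fit_reml(y, np.ones((a * r, 1)), {"g": np.repeat(np.arange(a), r)})
        Y = y.reshape(a, r)
        msb = r * np.sum((Y.mean(1) - y.mean()) ** 2) / (a - 1)
        msw = np.sum((Y - Y.mean(1, keepdims=True)) ** 2) / (a * (r - 1))
        s2g_anova = max((msb - msw) / r, 0.0)
        assert res.variances["g"] == pytest.approx(s2g_anova, rel=1e-6)
        assert res.variances["residual"] == pytest.approx(msw, rel=1e-6)

    def test_constant_response_gives_zero_variances(self):
        res = fit_reml(np.full(20, 3.0), np.ones((20, 1)), {"g": np.repeat(np.arange(5), 4)})
        assert all(v == 0 for v in res.variances.values())

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError):
            fit_reml(np.arange(6.0), np.ones((6, 1)), {"g": np.zeros(6)})


class TestDecomposition:
    def test_recovers_simulation_truth(self):
        geno = pg.simulate_genotypes(300, 300, seed=21)
        design = pg.simulate_trial_design(300, 2, 2, 2, 10, seed=21)
        spec = pg.TraitSpec("t", 1.0, 0.0, 0.0, 0.0, 1.0, env_means=(0.0,) * 4, n_qtl=150)
        rec, _ = pg.simulate_phenotypes(geno, design, spec, seed=21)
        vc = pg.decompose_variance(rec)
        assert 0.8 <= vc.var_geno <= 1.2
        assert vc.var_geno_year < 0.1 and vc.var_geno_nitro < 0.1
        assert 0.85 <= vc.var_resid <= 1.15

    def test_single_genotype_rejected(self):
        rec = make_records([1.0, 2.0])
        rec["genotype"] = "G0"
        with pytest.raises(ValueError):
            pg.decompose_variance(rec)

    def test_identical_values_give_zero_variances(self, small_panel):
        geno, design = small_panel
        spec = pg.TraitSpec("t", 0, 0, 0, 0, 0, env_means=(7.0,) * 4, n_qtl=5)
        rec, _ = pg.simulate_phenotypes(geno, design, spec, seed=1)
        vc = pg.decompose_variance(rec)
        assert vc.var_geno == 0 and vc.var_resid == 0

    def test_harmonic_means_full_design(self, df_dataset):
        *_, rec, _ = df_dataset[0], df_dataset[1], df_dataset[2], df_dataset[3]
        n_year, n_nitro, n_rep = design_harmonic_means(df_dataset[2])
        assert n_year == pytest.approx(2.0)
        assert n_nitro == pytest.approx(2.0)
        assert n_rep == pytest.approx(8.0)


class TestHeritability:
    def test_pure_genetic_variance_gives_one(self):
        vc = VarianceComponents("t", 1, 0, 0, 0, 0, 2, 2, 4)
        assert pg.broad_sense_heritability(vc) == 1.0

    def test_printed_formula_arithmetic(self):
        # 4 / (4 + 1/2 + 1/2 + 4/4) = 0.6667
        vc = VarianceComponents("t", 4, 1, 1, 0, 4, 2, 2, 4)
        assert pg.broad_sense_heritability(vc) == pytest.approx(4 / 6, abs=1e-4)

    def test_zero_genetic_variance_gives_zero(self):
        vc = VarianceComponents("t", 0, 1, 1, 0, 4, 2, 2, 4)
        assert pg.broad_sense_heritability(vc) == 0.0

    def test_all_zero_denominator_raises(self):
        vc = VarianceComponents("t", 0, 0, 0, 0, 0, 2, 2, 4)
        with pytest.raises(ZeroDivisionError):
            pg.broad_sense_heritability(vc)

    def test_scale_invariance(self, df_dataset):
        _, _, rec, _ = df_dataset
        vc1 = pg.decompose_variance(rec)
        rec2 = rec.copy()
        rec2["value"] *= 3.0
        vc2 = pg.decompose_variance(rec2)
        for f in ("var_geno", "var_geno_year", "var_geno_nitro", "var_block", "var_resid"):
            assert getattr(vc2, f) == pytest.approx(9 * getattr(vc1, f), rel=1e-3, abs=1e-8)
        h1 = pg.broad_sense_heritability(vc1)
        h2 = pg.broad_sense_heritability(vc2)
        assert h2 == pytest.approx(h1, abs=1e-6)

    def test_fraction_recovery_across_fig1_like_traits(self):
        """Mean bias of each variance fraction is small over replicated
        simulations at the default trait settings."""
        spec = pg.default_trait_specs()["HI"]
        total = (spec.var_geno + spec.var_geno_year + spec.var_geno_nitro
                 + spec.var_block + spec.var_resid)
        true_frac = np.array([spec.var_geno, spec.var_geno_year, spec.var_geno_nitro,
                              spec.var_block, spec.var_resid]) / total
        bias = np.zeros(5)
        n_rep = 6
        for seed in range(n_rep):
            geno = pg.simulate_genotypes(120, 200, seed=seed)
            design = pg.simulate_trial_design(120, 2, 2, 2, 6, seed=seed)
            rec, _ = pg.simulate_phenotypes(geno, design, spec, seed=seed)
            vc = pg.decompose_variance(rec)
            est = np.array([vc.var_geno, vc.var_geno_year, vc.var_geno_nitro,
                            vc.var_block, vc.var_resid])
            bias += est / est.sum() - true_frac
        assert np.all(np.abs(bias / n_rep) < 0.05)


class TestBlues:
    def test_balanced_no_block_variance_equals_genotype_mean(self, small_panel):
        geno, design = small_panel
        spec = pg.TraitSpec("t", 2.0, 0, 0, 0.0, 0.5, env_means=(5.0,) * 4, n_qtl=50)
        rec, _ = pg.simulate_phenotypes(geno, design, spec, seed=3)
        env = "2015-HN"
        blues = pg.compute_blues(rec, env)
        means = rec[rec["env"] == env].groupby("genotype")["value"].mean()
        merged = blues.set_index("genotype")["blue"]
        # with no block effects simulated, BLUEs shrink toward plot means
        assert np.corrcoef(merged.loc[means.index], means)[0, 1] > 0.999

    def test_single_plot_single_rep_returns_value(self):
        rec = make_records([1.0, 2.0, 3.0])
        blues = pg.compute_blues(rec, "2015-HN")
        np.testing.assert_allclose(sorted(blues["blue"]), [1, 2, 3])

    def test_recovery_with_low_noise(self, small_panel):
        geno, design = small_panel
        spec = pg.TraitSpec("t", 1.0, 0, 0, 0.3, 0.1, env_means=(0.0,) * 4, n_qtl=50)
        rec, truth = pg.simulate_phenotypes(geno, design, spec, seed=5)
        blues = pg.compute_blues(rec, "2016-LN").set_index("genotype")["blue"]
        gv = truth["genetic_values"].loc[blues.index]
        assert np.corrcoef(blues, gv)[0, 1] > 0.95

    def test_absent_genotype_not_imputed(self, df_dataset):
        _, _, rec, _ = df_dataset
        sub = rec[~((rec["env"] == "2015-HN") & (rec["genotype"] == "G001"))]
        blues = pg.compute_blues(sub, "2015-HN")
        assert "G001" not in set(blues["genotype"])


class TestEnvCorrelations:
    def test_identical_and_negated_blues(self):
        base = pd.DataFrame(
            dict(genotype=[f"G{i}" for i in range(6)], env="E1", trait="t",
                 blue=np.arange(6.0), se=0.1)
        )
        other = base.assign(env="E2")
        neg = base.assign(env="E3", blue=-base["blue"])
        tab = pg.env_correlations(pd.concat([base, other, neg], ignore_index=True))
        tab = tab.set_index(["env_a", "env_b"])
        assert tab.loc[("E1", "E2"), "r"] == pytest.approx(1.0)
        assert tab.loc[("E1", "E3"), "r"] == pytest.approx(-1.0)

    def test_constant_vector_reported_missing(self):
        a = pd.DataFrame(dict(genotype=list("abcd"), env="E1", trait="t",
                              blue=[1.0, 1, 1, 1], se=0.1))
        b = pd.DataFrame(dict(genotype=list("abcd"), env="E2", trait="t",
                              blue=[1.0, 2, 3, 4], se=0.1))
        tab = pg.env_correlations(pd.concat([a, b], ignore_index=True))
        assert np.isnan(tab["r"]).all()

    def test_simulated_cross_env_correlation_in_range(self):
        """High-heritability trait with strong genetic correlation between
        environments shows BLUE correlations in the expected band."""
        rs = []
        for seed in range(6):
            geno = pg.simulate_genotypes(100, 300, seed=seed)
            design = pg.simulate_trial_design(100, 2, 2, 2, 5, seed=seed)
            # cross-env genetic correlation about 0.8 once interactions enter
            spec = pg.TraitSpec("t", 0.8, 0.1, 0.1, 0.05, 0.1, env_means=(0,) * 4, n_qtl=100)
            rec, _ = pg.simulate_phenotypes(geno, design, spec, seed=seed)
            blues = pd.concat(
                [pg.compute_blues(rec, e) for e in sorted(rec["env"].unique())],
                ignore_index=True,
            )
            tab = pg.env_correlations(blues)
            rs.append(tab["r"].mean())
        assert 0.6 <= np.median(rs) <= 0.95
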