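"""Sparse-testing cross-validation scenarios and predictive-ability comparison.

Fourteen scenarios over four environments (2 years x 2 nitrogen levels):

* 1-4   single environment, k-fold CV with k = 5 (80/20) or k = 2 (50/50);
* 5-10  one full training environment plus 0/10/50/80 % of a target
        environment's genotypes (sparse testing), the remainder validated;
* 11-14 two full training environments plus 0/50/80 % of a third.

Predictive ability (PA) is the Pearson correlation between predicted values
and the target environment's genotype BLUEs, replicated over independent
training-population draws (default 10) with partitions shared across models
within a replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinship import Kinship
from .models import ChainParams, build_kernels, fit_gibbs

__all__ = [
    "ScenarioSpec",
    "PAResult",
    "make_scenarios",
    "partition",
    "run_scenario",
    "predictive_ability",
    "compare_models",
]

SINGLE_ENV_FRACTIONS = (2, 5)            # k-fold choices
TWO_ENV_FRACTIONS = (0.0, 0.10, 0.50, 0.80)
THREE_ENV_FRACTIONS = (0.0, 0.50, 0.80)


@dataclass
class ScenarioSpec:
    scenario_id: int
    full_tp_environments: list[str]
    target_environment: str
    target_fractions: tuple = ()
    k_folds: tuple = ()

    def __post_init__(self):
        if self.target_environment in self.full_tp_environments:
            raise ValueError("target environment cannot also be a full TP environment")
        if self.k_folds and self.full_tp_environments:
            raise ValueError("k-fold scenarios use a single environment")

    @property
    def environments(self) -> list[str]:
        return self.full_tp_environments + [self.target_environment]

    @property
    def n_environments(self) -> int:
        return len(self.environments)


@dataclass
class PAResult:
    """Tidy per-replicate predictive abilities plus a mean +/- sd summary."""

    table: pd.DataFrame      # scenario, model, info, fraction, replicate, pa
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self):
        g = self.table.groupby(["scenario", "model", "info", "fraction"], dropna=False)
        self.summary = g["pa"].agg(["mean", "std", "count"]).reset_index()


def make_scenarios(environments: list[str]) -> list[ScenarioSpec]:
    """The 14 standard scenarios for an ordered list of exactly 4 environments
    (ordering convention: [2015-HN, 2015-LN, 2016-HN, 2016-LN])."""
    if len(environments) != 4:
        raise ValueError("the standard scenario table needs exactly 4 environments")
    e = list(environments)
    specs = [
        ScenarioSpec(i + 1, [], e[i], k_folds=SINGLE_ENV_FRACTIONS) for i in range(4)
    ]
    two_env = [(e[0], e[1]), (e[1], e[0]), (e[0], e[2]), (e[2], e[3]), (e[3], e[2]), (e[1], e[3])]
    for i, (full, target) in enumerate(two_env):
        specs.append(ScenarioSpec(5 + i, [full], target, target_fractions=TWO_ENV_FRACTIONS))
    three_env = [
        ([e[0], e[1]], e[2]),
        ([e[0], e[1]], e[3]),
        ([e[0], e[3]], e[2]),
        ([e[1], e[2]], e[3]),
    ]
    for i, (full, target) in enumerate(three_env):
        specs.append(ScenarioSpec(11 + i, full, target, target_fractions=THREE_ENV_FRACTIONS))
    return specs


def partition(
    spec: ScenarioSpec,
    genotype_ids: list[str],
    fraction_or_k,
    replicate_seed: int,
):
    """Draw the training/validation split for one replicate.

    Single-environment scenarios return a list of k folds (VP id lists) whose
    union is the whole panel; multi-environment scenarios return
    (tp_ids, vp_ids) for the target environment.  Deterministic per seed.
    """
    rng = np.random.default_rng(replicate_seed)
    ids = np.asarray(genotype_ids)
    if spec.k_folds:
        k = int(fraction_or_k)
        if k not in spec.k_folds:
            raise ValueError(f"k={k} not valid for scenario {spec.scenario_id}")
        order = rng.permutation(ids)
        return [list(f) for f in np.array_split(order, k)]
    frac = float(fraction_or_k)
    if frac not in spec.target_fractions:
        raise ValueError(f"fraction {frac} not valid for scenario {spec.scenario_id}")
    n_tp = int(round(frac * ids.size))
    if n_tp >= ids.size:
        raise ValueError("fraction leaves an empty validation population")
    order = rng.permutation(ids)
    return list(order[:n_tp]), list(order[n_tp:])


def predictive_ability(predicted, observed) -> float:
    """Pearson correlation between predictions and observed BLUEs (NaN if degenerate)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    ok = ~(np.isnan(predicted) | np.isnan(observed))
    if ok.sum() < 3:
        warnings.warn("fewer than 3 prediction pairs; PA undefined")
        return np.nan
    if np.std(predicted[ok]) == 0 or np.std(observed[ok]) == 0:
        warnings.warn("constant predictions or observations; PA undefined")
        return np.nan
    return float(stats.pearsonr(predicted[ok], observed[ok])[0])


def _stack_blues(blues: pd.DataFrame, environments: list[str]) -> pd.DataFrame:
    sub = blues[blues["env"].isin(environments)]
    genos = sorted(sub["genotype"].unique())
    rows = []
    for e in environments:
        env_tab = sub[sub["env"] == e].set_index("genotype")["blue"]
        for g in genos:
            rows.append(dict(genotype=g, env=e, blue=env_tab.get(g, np.nan)))
    return pd.DataFrame(rows)


def _admissible_hrms(
    hrms: dict[str, Kinship] | None,
    spec: ScenarioSpec,
    fraction,
) -> dict[str, Kinship] | None:
    """NIRS datasets usable for a run: TP environments always; the target
    environment only when some of its genotypes are phenotyped in the TP."""
    if hrms is None:
        return None
    envs = list(spec.full_tp_environments)
    if spec.k_folds or (fraction is not None and float(fraction) > 0):
        envs.append(spec.target_environment)
    out = {e: hrms[e] for e in envs if e in hrms}
    return out


def run_scenario(
    spec: ScenarioSpec,
    model: str,
    info: str,
    blues: pd.DataFrame,
    grm: Kinship | None = None,
    hrms: dict[str, Kinship] | None = None,
    chain: ChainParams | None = None,
    n_replicates: int = 10,
    master_seed: int = 0,
    fractions=None,
) -> PAResult:
    """Replicated predictive-ability evaluation of one scenario.

    ``blues`` is a tidy table (genotype, env, trait, blue) for one trait.
    Replicate r of scenario s draws its partition with seed
    ``master_seed + 1000*s + r``, so partitions are reproducible and shared
    across models fitted with the same master seed.
    """
    if chain is None:
        chain = ChainParams.fast()
    stacked = _stack_blues(blues, spec.environments)
    genos = sorted(stacked["genotype"].unique())
    todo = fractions if fractions is not None else (
        list(spec.k_folds) if spec.k_folds else list(spec.target_fractions)
    )
    rows = []
    for frac in todo:
        for rep in range(1, n_replicates + 1):
            seed = master_seed + 1000 * spec.scenario_id + rep
            preds, obs = _run_once(spec, model, info, stacked, genos, grm, hrms,
                                   chain, frac, seed)
            rows.append(
                dict(scenario=spec.scenario_id, model=model, info=info,
                     fraction=frac, replicate=rep, pa=predictive_ability(preds, obs))
            )
    return PAResult(table=pd.DataFrame(rows))


def _run_once(spec, model, info, stacked, genos, grm, hrms, chain, frac, seed):
    """One replicate: build mask, fit, pool VP predictions, return (pred, obs)."""
    is_target = (stacked["env"] == spec.target_environment).to_numpy()
    y = stacked["blue"].to_numpy(dtype=float)
    use_hrms = _admissible_hrms(hrms, spec, None if spec.k_folds else frac)

    if spec.k_folds:
        folds = partition(spec, genos, frac, seed)
        assert sorted(g for f in folds for g in f) == list(genos), "folds must cover the panel"
        preds = pd.Series(index=genos, dtype=float)
        for fold in folds:
            mask = stacked["genotype"].isin(fold).to_numpy() & is_target
            _check_leakage(stacked, mask, fold, spec.target_environment)
            fit = _fit(y, mask, model, info, grm, use_hrms, stacked, chain, seed)
            p = fit.predictions.set_index("genotype")["predicted"]
            preds.loc[fold] = p.loc[fold].to_numpy()
        obs = stacked[is_target].set_index("genotype")["blue"].loc[genos]
        return preds.to_numpy(), obs.to_numpy()

    tp_ids, vp_ids = partition(spec, genos, frac, seed)
    mask = stacked["genotype"].isin(vp_ids).to_numpy() & is_target
    _check_leakage(stacked, mask, vp_ids, spec.target_environment)
    fit = _fit(y, mask, model, info, grm, use_hrms, stacked, chain, seed)
    p = fit.predictions.set_index("genotype")["predicted"]
    obs = stacked[is_target].set_index("genotype")["blue"]
    return p.loc[vp_ids].to_numpy(), obs.loc[vp_ids].to_numpy()


def _check_leakage(stacked, mask, vp_ids, target_env):
    """No (genotype, target-environment) response may be both trained on and predicted."""
    vp = set(vp_ids)
    in_tp = stacked[~mask]
    leak = in_tp[(in_tp["env"] == target_env) & in_tp["genotype"].isin(vp)]
    if len(leak) and not leak["blue"].isna().all():
        raise AssertionError("training/validation leakage in the target environment")


def _fit(y, mask, model, info, grm, hrms, stacked, chain, seed):
    # missing BLUEs (genotype absent from an environment) are masked too, but
    # excluded from PA because only VP targets are scored
    mask = mask | np.isnan(y)
    use_model = model
    if model != "SM" and stacked["env"].nunique() == 1:
        use_model = model  # MM/MDs degenerate naturally to SM structure
    if model == "SM" and stacked["env"].nunique() > 1:
        raise ValueError("SM cannot be fitted on a multi-environment stack")
    ks = build_kernels(use_model, info, grm=grm, hrms=hrms,
                       index=stacked[["genotype", "env"]], observed=~mask)
    chain_r = ChainParams(
        burn_in=chain.burn_in, n_iter=chain.n_iter, thin=chain.thin,
        seed=seed, prior_df=chain.prior_df, prior_r2=chain.prior_r2,
        fixed_variances=chain.fixed_variances,
    )
    return fit_gibbs(np.nan_to_num(y), mask, ks, chain_r)


def compare_models(pa_table: pd.DataFrame, factors: list[str]) -> dict:
    """Fisher-z comparison of predictive abilities across design factors.

    Applies z = atanh(r), fits an additive fixed-effects linear model of z on
    the requested factors, and reports back-transformed factor-level means plus
    Tukey-adjusted pairwise contrasts per factor.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    valid = [f for f in factors if f in pa_table.columns]
    if not valid:
        raise ValueError("no valid comparison factors")
    df = pa_table.dropna(subset=["pa"]).copy()
    r = df["pa"].clip(-1 + 1e-12, 1 - 1e-12)
    if (df["pa"].abs() >= 1).any():
        warnings.warn("|r| = 1 encountered; clipped before the z-transform")
    df["z"] = np.arctanh(r)
    usable = [f for f in valid if df[f].nunique() > 1]
    if not usable:
        raise ValueError("need >= 2 levels of at least one factor")
    formula = "z ~ " + " + ".join(f"C({f})" for f in usable)
    fit = smf.ols(formula, data=df).fit()

    level_means = {}
    contrasts = {}
    for f in usable:
        means = df.groupby(f)["z"].mean()
        level_means[f] = pd.DataFrame(
            {"z_mean": means, "pa_mean": np.tanh(means)}
        ).reset_index()
        tk = pairwise_tukeyhsd(df["z"].to_numpy(), df[f].astype(str).to_numpy())
        contrasts[f] = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    return {"ols": fit, "level_means": level_means, "contrasts": contrasts}
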