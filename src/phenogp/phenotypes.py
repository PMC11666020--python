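"""Plot-level phenotype analysis for multi-environment trials.

Covers the field-trial workflow: Tukey boxplot outlier flagging per
environment, REML variance decomposition of the split-block model, broad-sense
heritability from variance components and harmonic replication counts,
per-environment genotype BLUEs, and between-environment BLUE correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reml import RemlResult, fit_reml

__all__ = [
    "VarianceComponents",
    "flag_outliers",
    "decompose_variance",
    "broad_sense_heritability",
    "compute_blues",
    "env_correlations",
    "tukey_hinges",
]

REQUIRED_COLUMNS = ["genotype", "year", "nitro", "rep", "block", "trait", "value"]


@dataclass
class VarianceComponents:
    """REML variance decomposition of one trait plus design summaries.

    Harmonic means follow the heritability convention: N_Year and N_Nitro are
    harmonic means over genotypes of the number of years / nitrogen levels in
    which each genotype was observed; N_R is the harmonic mean of the number of
    replicate plots per genotype across all year x nitrogen cells.
    """

    trait: str
    var_geno: float
    var_geno_year: float
    var_geno_nitro: float
    var_block: float
    var_resid: float
    n_year: float
    n_nitro: float
    n_rep: float
    fixed_effects: dict = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0
    reml: RemlResult | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "var_geno": self.var_geno,
                "var_geno_year": self.var_geno_year,
                "var_geno_nitro": self.var_geno_nitro,
                "var_block": self.var_block,
                "var_resid": self.var_resid,
            },
            name=self.trait,
        )


def tukey_hinges(x: np.ndarray) -> tuple[float, float]:
    """Lower/upper hinges as in classic boxplot statistics (median-of-halves).

    On small samples these differ from interpolated quantiles; the boxplot
    convention is used deliberately for the outlier rule.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    half = (n + 1) // 2
    return float(np.median(x[:half])), float(np.median(x[n - half:]))


def flag_outliers(records: pd.DataFrame, coef: float = 1.5) -> pd.Series:
    """Boxplot-rule outlier flags per (environment, trait); records are never removed.

    A value is flagged when it lies outside [lower hinge - coef*IQR,
    upper hinge + coef*IQR], with the IQR taken between Tukey hinges.  Groups
    with fewer than 4 observations are left unflagged with a warning.
    """
    if coef <= 0:
        raise ValueError("coef must be positive")
    flags = pd.Series(False, index=records.index, name="outlier")
    for (env, trait), grp in records.groupby(["env", "trait"]):
        vals = grp["value"].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        if ok.sum() < 4:
            warnings.warn(f"group ({env}, {trait}) has < 4 observations; no outlier flags")
            continue
        lo, hi = tukey_hinges(vals[ok])
        iqr = hi - lo
        out = (vals < lo - coef * iqr) | (vals > hi + coef * iqr)
        flags.loc[grp.index[np.where(ok, out, False)]] = True
    return flags


def _harmonic_mean(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        return np.nan
    return counts.size / np.sum(1.0 / counts)


def design_harmonic_means(records: pd.DataFrame) -> tuple[float, float, float]:
    """(N_Year, N_Nitro, N_R) from realized per-genotype counts."""
    by_geno = records.groupby("genotype")
    n_year = _harmonic_mean(by_geno["year"].nunique().to_numpy())
    n_nitro = _harmonic_mean(by_geno["nitro"].nunique().to_numpy())
    n_rep = _harmonic_mean(by_geno.size().to_numpy())
    return n_year, n_nitro, n_rep


def _fixed_design(records: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + Year + Nitro + Rep(Nitro(Year)) treatment-coded dummies."""
    df = records
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in ("year", "nitro"):
        levels = sorted(df[f].unique())
        for lev in levels[1:]:
            cols.append((df[f] == lev).to_numpy(dtype=float))
            names.append(f"{f}[{lev}]")
    # replicate nested in year x nitro: one dummy per extra rep within each cell
    cells = df[["year", "nitro"]].drop_duplicates().itertuples(index=False)
    for year, nitro in cells:
        sub = df[(df["year"] == year) & (df["nitro"] == nitro)]
        for rep in sorted(sub["rep"].unique())[1:]:
            cols.append(
                ((df["year"] == year) & (df["nitro"] == nitro) & (df["rep"] == rep)).to_numpy(dtype=float)
            )
            names.append(f"rep[{rep}]@{year}-{nitro}")
    return np.column_stack(cols), names


def decompose_variance(records: pd.DataFrame, trait: str | None = None) -> VarianceComponents:
    """REML variance decomposition of the split-block model.

    Model: value ~ Year + Nitro + Rep(Nitro(Year)) [fixed]
                 + Bl(Rep(Nitro(Year))) + geno + geno:Year + geno:Nitro + e [random].
    Rows with missing values are dropped per trait before fitting.
    """
    df = records if trait is None else records[records["trait"] == trait]
    if trait is None:
        traits = df["trait"].unique()
        if len(traits) != 1:
            raise ValueError("records contain multiple traits; pass trait=")
        trait = traits[0]
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    if df["genotype"].nunique() < 2:
        raise ValueError("need >= 2 genotype levels to estimate genetic variance")

    X, names = _fixed_design(df)
    labels = {
        "block": (df["year"].astype(str) + "/" + df["nitro"].astype(str) + "/r"
                  + df["rep"].astype(str) + "/b" + df["block"].astype(str)).to_numpy(),
        "geno": df["genotype"].to_numpy(),
    }
    if df["year"].nunique() > 1:
        labels["geno_year"] = (df["genotype"].astype(str) + ":" + df["year"].astype(str)).to_numpy()
    if df["nitro"].nunique() > 1:
        labels["geno_nitro"] = (df["genotype"].astype(str) + ":" + df["nitro"].astype(str)).to_numpy()

    res = fit_reml(df["value"].to_numpy(dtype=float), X, labels)
    if not res.converged:
        warnings.warn(f"variance decomposition for {trait} did not converge")
    n_year, n_nitro, n_rep = design_harmonic_means(df)
    return VarianceComponents(
        trait=trait,
        var_geno=res.variances["geno"],
        var_geno_year=res.variances.get("geno_year", 0.0),
        var_geno_nitro=res.variances.get("geno_nitro", 0.0),
        var_block=res.variances["block"],
        var_resid=res.variances["residual"],
        n_year=n_year,
        n_nitro=n_nitro,
        n_rep=n_rep,
        fixed_effects=dict(zip(names, res.beta)),
        converged=res.converged,
        n_iter=res.n_iter,
        reml=res,
    )


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """H2 = s2_geno / (s2_geno + s2_geno:Year/N_Year + s2_geno:Nitro/N_Nitro + s2_e/N_R)."""
    denom = (
        vc.var_geno
        + vc.var_geno_year / vc.n_year
        + vc.var_geno_nitro / vc.n_nitro
        + vc.var_resid / vc.n_rep
    )
    if denom == 0:
        raise ZeroDivisionError("all variance components are zero; H2 undefined")
    return vc.var_geno / denom


def compute_blues(records: pd.DataFrame, environment: str, trait: str | None = None) -> pd.DataFrame:
    """Per-environment genotype BLUEs: genotype fixed, Rep and Bl(Rep) random.

    Returns a table (genotype, env, trait, blue, se) on the trait scale
    (cell-means coding: each genotype's fixed effect is its adjusted mean).
    Genotypes without plots in the environment are simply absent.
    """
    df = records[records["env"] == environment]
    if trait is not None:
        df = df[df["trait"] == trait]
    traits = df["trait"].unique()
    if len(traits) != 1:
        raise ValueError("records contain multiple traits; pass trait=")
    trait = traits[0]
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no records for environment {environment!r}")

    genos = sorted(df["genotype"].unique())
    gi = {g: i for i, g in enumerate(genos)}
    X = np.zeros((len(df), len(genos)))
    X[np.arange(len(df)), df["genotype"].map(gi)] = 1.0

    labels = {}
    if df["rep"].nunique() > 1:
        labels["rep"] = df["rep"].to_numpy()
        labels["block"] = ("r" + df["rep"].astype(str) + "/b" + df["block"].astype(str)).to_numpy()
    if not labels:
        # single replicate and block: BLUE is the plot value itself
        out = df.groupby("genotype", as_index=False)["value"].mean()
        return pd.DataFrame(
            dict(genotype=out["genotype"], env=environment, trait=trait,
                 blue=out["value"], se=np.nan)
        )
    res = fit_reml(df["value"].to_numpy(dtype=float), X, labels)
    return pd.DataFrame(
        dict(genotype=genos, env=environment, trait=trait, blue=res.beta, se=res.beta_se)
    )


def blues_all_environments(records: pd.DataFrame, trait: str | None = None) -> pd.DataFrame:
    tables = [compute_blues(records, env, trait) for env in sorted(records["env"].unique())]
    return pd.concat(tables, ignore_index=True)


def env_correlations(blues: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of genotype BLUEs between environments.

    One row per (trait, env_a, env_b) with r, p-value and the common-genotype
    count; degenerate pairs (constant vector, < 3 genotypes) report NaN.
    """
    rows = []
    for trait, sub in blues.groupby("trait"):
        wide = sub.pivot(index="genotype", columns="env", values="blue")
        envs = list(wide.columns)
        for i, a in enumerate(envs):
            for b in envs[i + 1:]:
                pair = wide[[a, b]].dropna()
                if len(pair) < 3 or pair[a].std() == 0 or pair[b].std() == 0:
                    r, p = np.nan, np.nan
                else:
                    r, p = stats.pearsonr(pair[a], pair[b])
                rows.append(dict(trait=trait, env_a=a, env_b=b, r=r, p=p, n=len(pair)))
    return pd.DataFrame(rows)
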