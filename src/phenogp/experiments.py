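"""Replicable study-condition experiments on synthetic data.

These functions bundle the full pipeline (simulate -> BLUEs -> spectral BLUPs
-> kinships -> kernel models) into the qualitative contrasts the method is
known for:

* sparse testing: does including part of the target environment's genotypes in
  the training population raise predictive ability for the held-out rest?
* environment scaling: how does predictive ability grow as 1 -> 2 -> 3
  environments enter the training population, for genomic vs phenomic kernels?

Comparisons are paired: within a replicate every configuration is scored on
the same validation genotypes, which removes validation-set composition noise
from the contrasts.

Scales are desk-sized versions of the motivating field study (about 100
genotypes, 800 markers, 300 wavelengths at a 5 nm step instead of 1,500 at
1 nm); the derivative window is chosen scale-equivalent (65 nm).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .kinship import grm_vanraden, hrm
from .models import ChainParams, build_kernels, fit_gibbs
from .phenotypes import blues_all_environments
from .simulate import (
    SpectraSpec,
    default_trait_specs,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_spectra,
    simulate_trial_design,
)
from .spectra import preprocess, spectra_blups

__all__ = ["SyntheticStudy", "sparse_testing_gain", "env_scaling_pa"]

ENVS = ["2015-HN", "2015-LN", "2016-HN", "2016-LN"]


def pool_predictions(parts: list[pd.Series]) -> pd.Series:
    """Concatenate per-fit predictions, centering each fit first.

    Different fits land on slightly different intercepts (the dominant
    between-fit artifact when pooling cross-validation folds); centering
    removes it without rescaling, so a fold whose predictions are strongly
    shrunken stays flat instead of having its noise inflated to unit scale.
    """
    return pd.concat([p - p.mean() for p in parts])

#: synthetic spectra grid: 300 points, 5 nm step over the NIR band
N_WL = 300
SG_WINDOW = 13  # 65 nm at the 5 nm step


class SyntheticStudy:
    """One synthetic dataset at study-like conditions, with derived products."""

    def __init__(self, seed: int, trait: str = "GY", n_geno: int = 100,
                 n_markers: int = 800, n_blocks: int = 5,
                 spectra_h2: float = 0.8, n_wl: int = N_WL):
        self.seed = seed
        self.trait = trait
        self.geno = simulate_genotypes(n_geno, n_markers, seed=seed)
        self.design = simulate_trial_design(n_geno, n_blocks=n_blocks, seed=seed)
        spec = default_trait_specs()[trait]
        self.records, self.truth = simulate_phenotypes(self.geno, self.design, spec, seed=seed)
        self.blues = blues_all_environments(self.records)
        self.grm = grm_vanraden(self.geno)
        sspec = SpectraSpec(
            n_wavelengths=n_wl,
            wavelength_grid=np.linspace(1000, 2500, n_wl, endpoint=False),
            target_h2_profile=np.full(n_wl, spectra_h2),
        )
        self.spectra, self.spectra_truth = simulate_spectra(self.geno, self.design, sspec, seed=seed)
        self._hrms = None

    @property
    def hrms(self):
        if self._hrms is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pre = preprocess(self.spectra, "der2", window=SG_WINDOW)
                self._hrms = {
                    e: hrm(spectra_blups(pre, e, share_window=3)) for e in ENVS
                }
        return self._hrms

    def stacked(self, envs: list[str]) -> pd.DataFrame:
        genos = sorted(self.blues["genotype"].unique())
        rows = []
        for e in envs:
            tab = self.blues[self.blues["env"] == e].set_index("genotype")["blue"]
            for g in genos:
                rows.append(dict(genotype=g, env=e, blue=tab.get(g, np.nan)))
        return pd.DataFrame(rows)

    def split_target(self, frac_tp: float, rep_seed: int):
        genos = sorted(self.blues["genotype"].unique())
        order = np.random.default_rng(rep_seed).permutation(genos)
        n_tp = int(round(frac_tp * len(genos)))
        return list(order[:n_tp]), list(order[n_tp:])

    def target_blues(self, target: str) -> pd.Series:
        return self.blues[self.blues["env"] == target].set_index("genotype")["blue"]

    def fit_predict(self, envs: list[str], target: str, mask_ids: list[str], info: str,
                    model: str, chain_seed: int,
                    hrm_envs: list[str] | None = None) -> pd.Series:
        """Mask ``mask_ids`` in the target environment, fit, return their predictions."""
        stacked = self.stacked(envs)
        y = stacked["blue"].to_numpy(float)
        is_t = (stacked["env"] == target).to_numpy()
        mask = is_t & stacked["genotype"].isin(mask_ids).to_numpy()
        mask = mask | np.isnan(y)
        hr = None
        if info in ("PP", "GP+PP"):
            hr = {e: self.hrms[e] for e in (hrm_envs if hrm_envs is not None else envs)}
        ks = build_kernels(model, info, grm=self.grm if info in ("GP", "GP+PP") else None,
                           hrms=hr, index=stacked[["genotype", "env"]], observed=~mask)
        fit = fit_gibbs(np.nan_to_num(y), mask, ks, ChainParams.fast(seed=chain_seed))
        p = fit.predictions
        p = p[p["env"] == target].set_index("genotype")["predicted"]
        return p.loc[[g for g in mask_ids if g in p.index]]


def sparse_testing_gain(seed: int, trait: str = "GY", info: str = "GP",
                        train_env: str = "2015-HN", target_env: str = "2016-HN",
                        n_geno: int = 100) -> dict:
    """Paired predictive abilities at 0 % vs 50 % target-environment inclusion.

    Training always contains the full ``train_env``; the contrast adds half the
    panel's records in ``target_env``, scoring both fits on the same held-out
    half.  Uses the GxE deviation model (MDs).
    """
    study = SyntheticStudy(seed, trait=trait, n_geno=n_geno)
    half_a, half_b = study.split_target(0.5, rep_seed=seed * 1000 + 1)
    envs = [train_env, target_env]
    all_ids = sorted(set(half_a) | set(half_b))
    obs = study.target_blues(target_env)
    hrms0 = [train_env]                       # target spectra unavailable at 0 %
    # 0 %: the whole target environment is masked, every genotype predicted at once
    p0 = study.fit_predict(envs, target_env, all_ids, info, "MDs",
                           chain_seed=seed * 17 + 1, hrm_envs=hrms0)
    # 50 %: complementary halves observed in turn; pooled predictions cover everyone
    p50 = pool_predictions([
        study.fit_predict(envs, target_env, half_b, info, "MDs",
                          chain_seed=seed * 17 + 2, hrm_envs=envs),
        study.fit_predict(envs, target_env, half_a, info, "MDs",
                          chain_seed=seed * 17 + 3, hrm_envs=envs),
    ])
    pa0 = float(np.corrcoef(p0.loc[all_ids], obs.loc[all_ids])[0, 1])
    pa50 = float(np.corrcoef(p50.loc[all_ids], obs.loc[all_ids])[0, 1])
    return {"pa0": pa0, "pa50": pa50, "gain": pa50 - pa0}


def env_scaling_pa(seed: int, trait: str = "DF", target_env: str = "2016-HN",
                   n_geno: int = 100) -> dict:
    """PA with 1, 2 or 3 training environments, paired on one validation subset.

    Follows the standard construction: the single-environment case is a
    five-fold split (80 % of the target's genotypes train, 20 % validate, SM
    model); the multi-environment cases add full extra environments to a
    training set holding 50 % of the target (MDs model).  All configurations
    are scored on the same 20 % validation genotypes.  Returns
    {(info, n_env): pa} for genomic and phenomic kernels.
    """
    extras = [e for e in ENVS if e != target_env]
    study = SyntheticStudy(seed, trait=trait, n_geno=n_geno, spectra_h2=0.8)
    genos = sorted(study.blues["genotype"].unique())
    obs = study.target_blues(target_env)
    order = list(np.random.default_rng(seed * 1000 + 7).permutation(genos))
    folds = [list(f) for f in np.array_split(np.asarray(order), 5)]
    halves = [order[: len(order) // 2], order[len(order) // 2:]]
    out = {}
    for n_env in (1, 2, 3):
        envs = extras[: n_env - 1] + [target_env]
        model = "SM" if n_env == 1 else "MDs"
        parts = folds if n_env == 1 else halves   # 5-fold CV vs 50 % inclusion
        for info in ("GP", "PP", "GP+PP"):
            preds = pool_predictions([
                study.fit_predict(envs, target_env, part, info, model,
                                  chain_seed=seed * 29 + 7 * n_env + i)
                for i, part in enumerate(parts)
            ])
            out[(info, n_env)] = float(np.corrcoef(preds.loc[genos], obs.loc[genos])[0, 1])
    return out
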