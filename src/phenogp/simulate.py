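"""Synthetic genotypes, trial designs, phenotypes and NIRS spectra.

Emulates a rice diversity-panel experiment: ~190 accessions grown in four
environments (2 years x 2 nitrogen levels) in a split-block design with two
replicates of 14 blocks each, genotyped at ~38k SNPs and phenotyped for six
traits, with plot-level near-infrared spectra (1,500 wavelengths, 1000-2500 nm)
on the harvested grain.  Every generator returns the underlying truth alongside
the observable data so downstream estimators can be tested for recovery.

Randomness: each operation derives its own stream from the master seed and a
fixed operation code via ``numpy.random.default_rng([seed, code])``, so outputs
are bit-reproducible per operation regardless of call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "TrialDesign",
    "TraitSpec",
    "SpectraSpec",
    "SpectraSet",
    "simulate_genotypes",
    "simulate_trial_design",
    "simulate_phenotypes",
    "simulate_spectra",
    "default_trait_specs",
    "default_spectra_spec",
    "env_label",
]

# fixed per-operation sub-stream codes (master seed stays the first word)
_SEED_GENO = 11
_SEED_DESIGN = 23
_SEED_PHENO = 37
_SEED_SPECTRA = 53


def env_label(year, nitro) -> str:
    """Canonical environment label, e.g. ``2015-HN``."""
    return f"{year}-{nitro}"


@dataclass
class GenotypeMatrix:
    """Biallelic dosage calls (individuals x markers), 0/1/2 with NaN = missing."""

    dosages: np.ndarray
    ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.ids), len(self.marker_ids)):
            raise ValueError("dosage shape does not match id/marker metadata")
        if self.chrom is None:
            self.chrom = np.ones(self.n_markers, dtype=int)
        if self.pos is None:
            self.pos = np.arange(1, self.n_markers + 1)
        if self.ref is None:
            self.ref = np.full(self.n_markers, "A")
        if self.alt is None:
            self.alt = np.full(self.n_markers, "T")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def het_rate(self) -> np.ndarray:
        """Fraction of non-missing calls that are heterozygous, per marker."""
        called = ~np.isnan(self.dosages)
        het = (self.dosages == 1) & called
        with np.errstate(invalid="ignore"):
            return np.where(called.sum(0) > 0, het.sum(0) / called.sum(0), 0.0)

    def maf(self) -> np.ndarray:
        """Realized minor-allele frequency per marker from non-missing calls."""
        p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep].copy(),
            ids=list(self.ids),
            marker_ids=[self.marker_ids[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.marker_ids[i] for i in keep],
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            ref=self.ref[keep],
            alt=self.alt[keep],
        )


@dataclass
class TrialDesign:
    """Randomized field layout over environments, replicates and blocks."""

    genotype_ids: list[str]
    environments: list[tuple]              # (year, nitro) pairs
    replicates_per_env: int
    blocks_per_replicate: int
    plot_assignments: pd.DataFrame         # plot, genotype, year, nitro, env, rep, block

    def __post_init__(self):
        pa = self.plot_assignments
        if pa["plot"].duplicated().any():
            raise ValueError("duplicate plot keys in design")
        present = pa.groupby("env")["genotype"].nunique()
        for year, nitro in self.environments:
            lab = env_label(year, nitro)
            if present.get(lab, 0) < len(self.genotype_ids):
                raise ValueError(f"genotypes missing from environment {lab}")

    @property
    def env_labels(self) -> list[str]:
        return [env_label(y, n) for y, n in self.environments]

    @property
    def n_plots(self) -> int:
        return len(self.plot_assignments)


@dataclass
class TraitSpec:
    """Simulation truth for one trait: variance budget and environment means."""

    name: str
    var_geno: float
    var_geno_year: float
    var_geno_nitro: float
    var_block: float
    var_resid: float
    env_means: tuple
    n_qtl: int = 100

    def __post_init__(self):
        for f in ("var_geno", "var_geno_year", "var_geno_nitro", "var_block", "var_resid"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass
class SpectraSpec:
    """Simulation truth for plot-level reflectance curves.

    ``target_h2_profile`` is the wavelength heritability the generating
    components aim at (after accounting for the replicate count);
    ``genetic_loading`` in [0, 1] scales the marker-driven genotypic signal
    (0 means no genetic signal at all), ``rank`` the number of marker-driven
    latent factors shared with the trait QTL space.
    """

    n_wavelengths: int = 1500
    wavelength_grid: np.ndarray = None
    target_h2_profile: np.ndarray = None
    genetic_loading: float = 1.0
    env_shift_sd: float = 0.5
    noise_sd: float = 0.1
    rank: int = 20
    env_shift_lengthscale: float = 100.0   # nm
    loading_lengthscale: float = 40.0      # nm; absorption-feature scale, so
                                           # derivative preprocessing keeps the
                                           # genetic signal while removing the
                                           # broader environmental baselines
    noise_smooth_frac: float = 0.9         # share of plot-noise variance in smooth
                                           # scattering-like baselines (the rest is
                                           # white instrument noise)
    noise_lengthscale: float = 200.0       # nm
    env_gxe_frac: float = 0.3              # share of genotypic spectral variance that
                                           # is environment-specific (spectral GxE):
                                           # each environment sees a partly different
                                           # expression of the marker factors

    def __post_init__(self):
        if self.wavelength_grid is None:
            self.wavelength_grid = np.linspace(1000, 2499, self.n_wavelengths)
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        if self.wavelength_grid.size != self.n_wavelengths:
            raise ValueError("wavelength_grid length must equal n_wavelengths")
        if self.target_h2_profile is None:
            # smooth mid-range profile; real wavelength heritabilities vary in band
            x = np.linspace(0, 1, self.n_wavelengths)
            self.target_h2_profile = 0.45 + 0.25 * np.sin(2 * np.pi * x) ** 2
        self.target_h2_profile = np.asarray(self.target_h2_profile, dtype=float)
        if self.target_h2_profile.size != self.n_wavelengths:
            raise ValueError("target_h2_profile length must equal n_wavelengths")
        if np.any((self.target_h2_profile < 0) | (self.target_h2_profile > 1)):
            raise ValueError("target_h2_profile values must lie in [0, 1]")


@dataclass
class SpectraSet:
    """Plot-level reflectance rows on a shared wavelength grid."""

    data: pd.DataFrame                     # genotype, env, rep, block + wl columns
    wavelength_grid: np.ndarray
    preprocessing_tag: list = field(default_factory=list)

    @property
    def wl_columns(self) -> list[str]:
        return [f"wl_{int(round(w))}" for w in self.wavelength_grid]

    def matrix(self) -> np.ndarray:
        return self.data[self.wl_columns].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_geno: int,
    n_markers: int,
    maf_range=(0.042, 0.5),
    seed: int = 0,
    n_subpops: int = 4,
    fst: float = 0.25,
    admix_alpha: float = 0.3,
) -> GenotypeMatrix:
    """Draw dosages marker-wise as binomial(2, p) with ancestral p ~ U(maf_range).

    A diversity panel is structured, and genomic prediction of unphenotyped
    genotypes works through that structure, so by default each individual draws
    Dirichlet(``admix_alpha``) admixture proportions over ``n_subpops``
    ancestral groups whose marker frequencies are Balding-Nichols draws around
    the ancestral frequency at differentiation ``fst`` (rice subgroups are
    strongly differentiated and panels contain admixed accessions).  The
    individual dosage is binomial(2, q_i' p_s) at each marker.
    ``n_subpops=1`` or ``fst=0`` gives an unstructured Hardy-Weinberg panel.
    """
    if n_geno < 2 or n_markers < 1:
        raise ValueError("need n_geno >= 2 and n_markers >= 1")
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < min <= max <= 0.5")
    if fst < 0 or fst >= 1:
        raise ValueError("fst must lie in [0, 1)")
    rng = np.random.default_rng([seed, _SEED_GENO])
    p = rng.uniform(lo, hi, size=n_markers)
    if n_subpops > 1 and fst > 0:
        a = (1.0 - fst) / fst
        # per-ancestry frequencies: mean p, variance fst * p(1-p)
        ps = rng.beta(a * p, a * (1.0 - p), size=(n_subpops, n_markers))
        q = rng.dirichlet(np.full(n_subpops, admix_alpha), size=n_geno)
        dos = rng.binomial(2, np.clip(q @ ps, 1e-6, 1 - 1e-6)).astype(float)
    else:
        dos = rng.binomial(2, p, size=(n_geno, n_markers)).astype(float)
    return GenotypeMatrix(
        dosages=dos,
        ids=[f"G{i + 1:03d}" for i in range(n_geno)],
        marker_ids=[f"M{j + 1}" for j in range(n_markers)],
    )


def simulate_trial_design(
    n_geno: int,
    n_years: int = 2,
    n_nitro: int = 2,
    n_reps: int = 2,
    n_blocks: int = 14,
    seed: int = 0,
) -> TrialDesign:
    """Randomize every genotype once per replicate of each year x nitrogen cell.

    Genotypes are shuffled independently per (environment, replicate) and cut
    into ``n_blocks`` nearly equal blocks (uneven padding, never dropping).
    """
    if min(n_geno, n_years, n_nitro, n_reps, n_blocks) < 1:
        raise ValueError("all design counts must be >= 1")
    rng = np.random.default_rng([seed, _SEED_DESIGN])
    ids = [f"G{i + 1:03d}" for i in range(n_geno)]
    years = [2015 + i for i in range(n_years)]
    nitros = (["HN", "LN"] if n_nitro == 2 else [f"N{j + 1}" for j in range(n_nitro)])
    environments = [(y, t) for y in years for t in nitros]
    rows = []
    plot = 0
    for year, nitro in environments:
        for rep in range(1, n_reps + 1):
            order = rng.permutation(n_geno)
            blocks = np.array_split(order, n_blocks)
            for b, members in enumerate(blocks, start=1):
                for gi in members:
                    plot += 1
                    rows.append(
                        dict(
                            plot=f"P{plot:05d}",
                            genotype=ids[gi],
                            year=year,
                            nitro=nitro,
                            env=env_label(year, nitro),
                            rep=rep,
                            block=b,
                        )
                    )
    pa = pd.DataFrame(rows)
    return TrialDesign(
        genotype_ids=ids,
        environments=environments,
        replicates_per_env=n_reps,
        blocks_per_replicate=n_blocks,
        plot_assignments=pa,
    )


def _scale_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale a draw so its sample variance is exactly target_var."""
    if target_var <= 0:
        return np.zeros_like(x)
    x = x - x.mean()
    s = x.std()
    if s == 0:
        return np.zeros_like(x)
    return x * (np.sqrt(target_var) / s)


def simulate_phenotypes(
    geno: GenotypeMatrix,
    design: TrialDesign,
    spec: TraitSpec,
    seed: int = 0,
    structured_gxe: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Plot value = env mean + additive genetic value + GxYear + GxNitro + block + error.

    The additive genetic value is built from ``spec.n_qtl`` markers with normal
    effects and rescaled so its realized variance equals ``var_geno`` exactly.
    Interaction deviations are genetic too: by default each year / nitrogen
    level draws its own marker-based deviation (its own QTL effects, scaled to
    the spec variance), so genotype-by-environment effects are heritable and
    carry kinship structure - the property the GxE prediction kernels exploit.
    ``structured_gxe=False`` draws them i.i.d. per (genotype, level) cell
    instead.  Block and residual effects are i.i.d. normal.  Returns
    (records, truth) where truth carries every generated component for
    recovery tests.
    """
    if spec.n_qtl > geno.n_markers:
        raise ValueError("n_qtl exceeds available markers")
    if len(spec.env_means) != len(design.environments):
        raise ValueError("env_means length must equal the number of environments")
    rng = np.random.default_rng([seed, _SEED_PHENO, zlib.crc32(spec.name.encode())])
    n_g = geno.n_individuals
    ids = geno.ids

    def genetic_draw(var: float) -> np.ndarray:
        q = rng.choice(geno.n_markers, size=spec.n_qtl, replace=False)
        eff = rng.normal(size=spec.n_qtl)
        return _scale_to_var(geno.dosages[:, q] @ eff, var), q

    gv, qtl = genetic_draw(spec.var_geno)

    years = sorted({y for y, _ in design.environments})
    nitros = sorted({t for _, t in design.environments})

    def interaction_draws(levels, var):
        out = {}
        for lev in levels:
            if var <= 0:
                out[lev] = np.zeros(n_g)
            elif structured_gxe:
                out[lev] = genetic_draw(var)[0]
            else:
                out[lev] = rng.normal(0, np.sqrt(var), n_g)
        return out

    g_year = interaction_draws(years, spec.var_geno_year)
    g_nitro = interaction_draws(nitros, spec.var_geno_nitro)

    pa = design.plot_assignments
    block_keys = pa[["env", "rep", "block"]].drop_duplicates()
    block_eff = {
        tuple(r): (rng.normal(0, np.sqrt(spec.var_block)) if spec.var_block > 0 else 0.0)
        for r in block_keys.itertuples(index=False)
    }
    env_mean = {env_label(y, t): m for (y, t), m in zip(design.environments, spec.env_means)}
    gi = {g: i for i, g in enumerate(ids)}

    idx = pa["genotype"].map(gi).to_numpy()
    base = (
        pa["env"].map(env_mean).to_numpy()
        + gv[idx]
        + np.array([g_year[y][i] for y, i in zip(pa["year"], idx)])
        + np.array([g_nitro[t][i] for t, i in zip(pa["nitro"], idx)])
        + np.array([block_eff[(e, r, b)] for e, r, b in zip(pa["env"], pa["rep"], pa["block"])])
    )
    resid = rng.normal(0, np.sqrt(spec.var_resid), len(pa)) if spec.var_resid > 0 else np.zeros(len(pa))
    records = pa.copy()
    records["trait"] = spec.name
    records["value"] = base + resid

    truth = {
        "genetic_values": pd.Series(gv, index=ids, name=spec.name),
        "g_year": pd.DataFrame(g_year, index=ids),
        "g_nitro": pd.DataFrame(g_nitro, index=ids),
        "block_effects": block_eff,
        "residuals": resid,
        "qtl": qtl,
        "env_means": env_mean,
    }
    return records, truth


def _smooth_gp_curves(rng, grid: np.ndarray, lengthscale: float, n_curves: int) -> np.ndarray:
    """``n_curves`` unit-variance smooth curves over `grid` (squared-exponential
    covariance), sampled on a coarse grid and interpolated for speed."""
    step = max(lengthscale / 4.0, (grid[-1] - grid[0]) / 200.0)
    coarse = np.arange(grid[0], grid[-1] + step, step)
    d = coarse[:, None] - coarse[None, :]
    C = np.exp(-0.5 * (d / lengthscale) ** 2) + 1e-8 * np.eye(coarse.size)
    Z = np.linalg.cholesky(C) @ rng.normal(size=(coarse.size, n_curves))
    out = np.empty((n_curves, grid.size))
    for i in range(n_curves):
        out[i] = np.interp(grid, coarse, Z[:, i])
    return out


def _smooth_gp_curve(rng, grid: np.ndarray, lengthscale: float) -> np.ndarray:
    return _smooth_gp_curves(rng, grid, lengthscale, 1)[0]


def simulate_spectra(
    geno: GenotypeMatrix,
    design: TrialDesign,
    spec: SpectraSpec,
    seed: int = 0,
) -> tuple[SpectraSet, dict]:
    """Reflectance = genotype curve + environment shift + block effect + noise.

    The genotype curve is a low-rank linear combination of marker-driven latent
    factors (shared genetic basis with the trait QTL space), standardized per
    wavelength and scaled so the plug-in wavelength heritability of the
    generating components equals ``target_h2_profile`` when
    ``genetic_loading = 1``.  Environment shifts are wavelength-smooth
    (Gaussian-process draws, length-scale ``env_shift_lengthscale`` nm), which
    derivative preprocessing attenuates by design.  Block effects are flat
    across wavelengths with sd ``0.5 * noise_sd``.
    """
    rng = np.random.default_rng([seed, _SEED_SPECTRA])
    n_g = geno.n_individuals
    L = spec.n_wavelengths
    n_reps = design.replicates_per_env

    # marker-driven latent factors -> smooth loadings over wavelength
    # factor scores keep their natural covariance (proportional to the genomic
    # relationship), so the spectral similarity is a noisy proxy of kinship
    Zc = geno.dosages - geno.dosages.mean(axis=0, keepdims=True)
    W = rng.normal(size=(geno.n_markers, spec.rank)) / np.sqrt(geno.n_markers)
    T = Zc @ W
    T = T - T.mean(0)
    loadings = np.stack(
        [_smooth_gp_curve(rng, spec.wavelength_grid, spec.loading_lengthscale)
         for _ in range(spec.rank)]
    )
    raw = T @ loadings                                   # genotypes x wavelengths
    sd = raw.std(axis=0)
    raw = raw / np.where(sd > 0, sd, 1.0)

    # scale genetic sd per wavelength so H2 = s2g / (s2g + s2e/NR) hits the target
    h = np.clip(spec.target_h2_profile, 0.0, 0.995)
    s2e = spec.noise_sd**2
    s2g = h / (1.0 - h) * s2e / max(n_reps, 1)
    if spec.noise_sd == 0:
        s2g = h  # arbitrary positive scale; heritability is 1 wherever h > 0
    genetic = spec.genetic_loading * raw * np.sqrt(s2g)

    # environment-specific genotypic spectra: each environment expresses the
    # marker factors with partly different weights, so a single environment's
    # relationship matrix is a partial view of the shared genetic structure
    f = np.clip(spec.env_gxe_frac, 0.0, 1.0)
    genetic_env = {}
    for lab in design.env_labels:
        if f > 0:
            We = rng.normal(size=(geno.n_markers, spec.rank)) / np.sqrt(geno.n_markers)
            Te = Zc @ We
            Te = Te - Te.mean(0)
            rawe = Te @ loadings
            sde = rawe.std(axis=0)
            rawe = rawe / np.where(sde > 0, sde, 1.0)
            genetic_env[lab] = (
                np.sqrt(1.0 - f) * genetic
                + np.sqrt(f) * spec.genetic_loading * rawe * np.sqrt(s2g)
            )
        else:
            genetic_env[lab] = genetic

    env_shift = {
        lab: spec.env_shift_sd * _smooth_gp_curve(rng, spec.wavelength_grid, spec.env_shift_lengthscale)
        if spec.env_shift_sd > 0
        else np.zeros(L)
        for lab in design.env_labels
    }

    pa = design.plot_assignments
    block_keys = pa[["env", "rep", "block"]].drop_duplicates()
    block_sd = 0.5 * spec.noise_sd
    block_eff = {
        tuple(r): (rng.normal(0, block_sd) if block_sd > 0 else 0.0)
        for r in block_keys.itertuples(index=False)
    }
    gi = {g: i for i, g in enumerate(geno.ids)}
    idx = pa["genotype"].map(gi).to_numpy()

    M = np.empty((len(pa), L))
    env_arr = pa["env"].to_numpy()
    for lab in design.env_labels:
        rows = env_arr == lab
        M[rows] = genetic_env[lab][idx[rows]]
    M = M + np.stack([env_shift[e] for e in pa["env"]])
    M = M + np.array([block_eff[(e, r, b)] for e, r, b in zip(pa["env"], pa["rep"], pa["block"])])[:, None]
    if spec.noise_sd > 0:
        w = np.clip(spec.noise_smooth_frac, 0.0, 1.0)
        noise = np.sqrt(1.0 - w) * rng.normal(size=M.shape)
        if w > 0:
            noise += np.sqrt(w) * _smooth_gp_curves(
                rng, spec.wavelength_grid, spec.noise_lengthscale, len(pa)
            )
        M = M + spec.noise_sd * noise

    cols = [f"wl_{int(round(w))}" for w in spec.wavelength_grid]
    data = pd.concat(
        [pa[["genotype", "env", "rep", "block"]].reset_index(drop=True),
         pd.DataFrame(M, columns=cols)],
        axis=1,
    )
    truth = {
        "genetic_spectra": pd.DataFrame(genetic, index=geno.ids, columns=cols),
        "genetic_spectra_env": {lab: pd.DataFrame(genetic_env[lab], index=geno.ids, columns=cols)
                                for lab in design.env_labels},
        "env_shift": env_shift,
        "factor_scores": T,
        "target_h2": spec.target_h2_profile.copy(),
    }
    return SpectraSet(data=data, wavelength_grid=spec.wavelength_grid.copy()), truth


# ---------------------------------------------------------------------------
# study-condition defaults: six rice traits
# ---------------------------------------------------------------------------

def default_trait_specs(environments=None) -> dict[str, TraitSpec]:
    """Trait truth emulating the rice panel: variance fractions inside the
    reported decomposition ranges and totals from the descriptive statistics
    (DF 93.2 +/- 7.2 d, PH 102.5 +/- 16.6 cm, TGW 28.2 +/- 4.5 g, GY 4162 +/-
    1490 kg/ha, HI 0.46 +/- 0.08, GNC 1.56 +/- 0.18 %), with year and nitrogen
    mean shifts as printed (e.g. +15.7 cm PH and +0.40 % GNC under HN)."""
    if environments is None:
        environments = [(2015, "HN"), (2015, "LN"), (2016, "HN"), (2016, "LN")]

    def means(base, year_shift, hn_shift):
        out = []
        for y, t in environments:
            m = base
            if y == 2016:
                m += year_shift
            if t == "HN":
                m += hn_shift
            out.append(m)
        return tuple(out)

    def fracs(total, g, gy, gn, bl):
        resid = 1.0 - (g + gy + gn + bl)
        return dict(
            var_geno=g * total,
            var_geno_year=gy * total,
            var_geno_nitro=gn * total,
            var_block=bl * total,
            var_resid=resid * total,
        )

    return {
        "DF": TraitSpec("DF", env_means=means(93.2, -1.0, 0.0), **fracs(7.22**2, 0.60, 0.06, 0.02, 0.05)),
        "PH": TraitSpec("PH", env_means=means(102.5, 6.0, 15.7), **fracs(16.6**2, 0.70, 0.05, 0.02, 0.05)),
        "TGW": TraitSpec("TGW", env_means=means(28.2, 1.0, -0.51), **fracs(4.53**2, 0.80, 0.03, 0.01, 0.03)),
        "GY": TraitSpec("GY", env_means=means(4162.0, 600.0, 1111.0), **fracs(1490.0**2, 0.22, 0.18, 0.10, 0.10)),
        "HI": TraitSpec("HI", env_means=means(0.46, 0.02, -0.04), **fracs(0.08**2, 0.45, 0.10, 0.05, 0.05)),
        "GNC": TraitSpec("GNC", env_means=means(1.56, 0.05, 0.40), **fracs(0.18**2, 0.25, 0.13, 0.10, 0.04)),
    }


def default_spectra_spec(n_wavelengths: int = 1500) -> SpectraSpec:
    grid = np.linspace(1000, 2500, n_wavelengths, endpoint=False) if n_wavelengths != 1500 else np.arange(1000, 2500)
    return SpectraSpec(n_wavelengths=n_wavelengths, wavelength_grid=grid[:n_wavelengths])
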