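# Methods

This note documents the statistical models, the synthetic-data generator, and
the numerical and design choices behind `phenogp`.

## Plot-level phenotype analysis

Outliers are flagged per environment and trait with the classic boxplot rule:
values outside `[lower hinge − 1.5·IQR, upper hinge + 1.5·IQR]`, where the
hinges are Tukey's (medians of the data halves, not interpolated quantiles —
the two disagree on small samples, and the boxplot-statistics convention is
used deliberately). Flagged records are never removed.

Variance decomposition fits, by REML,

```
value ~ Year + Nitro + Rep(Nitro(Year))                          [fixed]
      + Bl(Rep(Nitro(Year))) + geno + geno:Year + geno:Nitro + e [random]
```

Broad-sense heritability is the plug-in
`H² = σ²g / (σ²g + σ²g:Y/N_Year + σ²g:N/N_Nitro + σ²e/N_R)` with `N_Year`,
`N_Nitro` harmonic means over genotypes of the number of years / nitrogen
levels each genotype was observed in, and `N_R` the harmonic mean of total
plots per genotype (8 in the complete 2×2×2 design). Genotypes missing from
a year contribute their own realized counts.

Per-environment genotype BLUEs use cell-means coding (genotype fixed,
replicate and block-in-replicate random), so BLUEs sit on the trait scale.
Rows with missing trait values are dropped per trait before fitting.
Between-environment correlations are pairwise-complete Pearson correlations
of the BLUEs; degenerate pairs report NaN.

### The REML engine

One engine (`phenogp.reml`) serves the variance decomposition, the BLUE
model, and the per-wavelength spectral model: average-information (AI) REML
on a unit-variance-rescaled response, with likelihood-guarded step halving,
a guaranteed-ascent EM fallback step when the AI direction fails, active-set
handling of components pinned at zero, and non-negativity by projection.
Convergence requires a relative change below 1e-8 in every component
(maximum 200 iterations; non-convergence is returned flagged, never
silently). Dense V-inverses are used throughout — trial sizes are a few
thousand plots at most, where dense algebra is both fast and robust. On
balanced one-way designs the engine reproduces the expected-mean-squares
closed form to 1e-6 relative (tested).

## Spectra

Preprocessing operates row-wise per plot spectrum: Savitzky–Golay smoothing,
SNV (standard normal variate), detrend (SNV + removal of a 2nd-order
polynomial baseline), and first/second derivatives of SNV-normalized rows
("normalization" is taken as SNV, the standard chemometric reading).
Derivatives use a Savitzky–Golay filter of window 37 points and polynomial
order 2 by default — on the instrument's 1 nm grid that is a 37 nm window,
wide enough to suppress grid-level noise while preserving absorption-band
shape. Both parameters are per-call options, and analyses on down-sampled
synthetic grids must choose a window of equivalent *physical* width (the
bundled experiments use 13 points on a 5 nm grid ≈ 65 nm). Derivative edges
are trimmed, never padded; the trimmed grid is recorded so the HRM's `L`
counts retained wavelengths only. The default retained pipeline is the
second derivative (der2): in these data the non-genetic plot effects are
smooth baselines, which differencing suppresses, while genetic absorption
features are narrow and survive.

Per environment and wavelength, the mixed model
`reflectance = µ + block(Rep) + geno + e` (block and genotype random) yields
genotype BLUPs `Sp*` and the wavelength heritability
`H² = σ²g / (σ²g + σ²e/N_R)`. Wavelengths are fitted independently by
default; `share_window=k` estimates variances on every k-th wavelength and
reuses the ratios for neighbours (one GLS solve each), trading little
accuracy (BLUP correlation > 0.98 at k = 4 in tests) for a large speed-up.
Technical scans, when present as a `scan` column, are averaged to plot level
before modelling.

## Relationship matrices

SNP QC drops markers with call rate < 80 %, heterozygosity > 20 % or
MAF < 2.5 %, then sets surviving heterozygous calls to missing (the rules
target inbred-line GBS data, where residual heterozygote calls are largely
errors). The GRM is VanRaden's `K = ZZ′ / 2Σpⱼ(1−pⱼ)` with observed allele
frequencies; monomorphic markers contribute nothing and are excluded from
the denominator; residual missing dosages are mean-imputed with a warning
(imputation proper is upstream of this package). The HRM is
`H = Sp*Sp*′ / L` exactly as defined — BLUPs are mean-zero by construction,
so `H` is already a centered cross-product; optional per-wavelength unit
scaling exists but is off, since the defining formula has none. Kinship
objects enforce symmetry (1e-10) and positive semi-definiteness (eigenvalues
below −1e-8 raise; those in (−1e-8, 0) are clipped with a warning).

## Prediction models

The SM/MM/MDs family is fitted by a Gibbs sampler over fixed effects (flat
prior), per-kernel random effects, variances (scaled-inverse-χ² priors,
df = 5), and the residual. Key choices:

* **Eigenbasis sampling.** Each kernel is eigendecomposed once (eigenvalues
  below 1e-10 of the maximum truncated); effect coefficients are sampled
  independently per eigen-direction, making sweeps O(n²) per kernel.
* **Kernel normalization.** Sampling operates on unit-mean-diagonal kernels,
  with variances reported back on the raw-kernel scale. Predictions are
  invariant; priors stay well-posed whatever the raw scale (a der2-spectra
  HRM has diagonal ~1e-10).
* **Priors.** The prior variance budget assigns `prior_r2 = 0.5` of the
  observed-response variance evenly across the genetic kernels and the rest
  to the residual, the convention of the kernel-regression software family
  this model class comes from.
* **Missing responses** are imputed by data augmentation each sweep — exact
  in distribution and simple; predictions are posterior means of the linear
  predictor, with per-position Monte-Carlo standard errors from
  autocorrelation-adjusted effective sample sizes.
* **Fully masked environments** get no fixed-effect indicator (their level
  aliases to the reference). Correlation-based predictive ability is
  invariant to this; the design stays estimable in 0 %-inclusion scenarios.
* **Chains.** The reference preset is burn-in 10,000 / 70,000 iterations /
  thin 10; the `fast` preset (500 / 3,000 / 5) is used in tests and the
  bundled experiments, where the sampler-vs-oracle agreement shows it
  suffices at these problem sizes.

`solve_blup` solves the same model at fixed variances through the penalized
least-squares (mixed-model-equation) system in the eigenbasis — an
independent closed-form oracle that the sampler is tested against (and which
itself is tested against direct conditional-Gaussian prediction from the
explicit joint covariance).

In the MDs model all G×E kernels of one family share a single variance (one
σ²G×E for the genomic block-diagonal, one per phenomic dataset). Under PP,
each NIRS environment contributes its own main (and, under MDs, G×E) random
effect; only environments whose spectra are available to the training
population contribute, and a target environment's spectra enter only when a
nonzero fraction of its genotypes is in training. GP+PP is the union of the
genomic and phenomic kernels — never a blended single matrix.

## Cross-validation engine

`make_scenarios` emits the 14 standard scenarios on four environments:
1–4 k-fold (k = 5 or 2) within one environment; 5–10 one full training
environment plus 0/10/50/80 % of a target; 11–14 two full environments plus
0/50/80 % of a third. Partitions are simple random draws, deterministic per
replicate seed (`master_seed + 1000·scenario + replicate`), shared across
models within a replicate so model contrasts are paired. A leakage guard
asserts on every run that no target-environment response is both trained on
and predicted. K-fold predictive ability pools all genotypes' predictions
within a replicate before correlating. `compare_models` Fisher-z-transforms
PA values (clipping |r| = 1 with a warning), fits an additive fixed-effects
model, and reports back-transformed level means plus Tukey-adjusted pairwise
contrasts.

## Synthetic data

The generator produces the statistical structure the pipeline assumes, at
configurable scale. Defaults mirror the motivating rice trial: 2 years × 2
nitrogen levels, split-block with 2 replicates of 14 blocks, six traits whose
variance fractions lie in the reported decomposition ranges with absolute
totals from the descriptive statistics (e.g. grain yield 4,162 ± 1,490 kg/ha
with ~22 % genotypic variance; days to flowering with ~60 %), and NIRS
spectra on a 1,000–2,500 nm grid.

* **Genotypes.** Marker dosages are binomial(2, p) draws; by default the
  panel is *structured*: each individual has Dirichlet(0.3) admixture
  proportions over 4 ancestral groups whose frequencies are Balding–Nichols
  draws at F_st = 0.25 around an ancestral frequency uniform on the MAF
  range. Relatedness is what makes prediction of unphenotyped genotypes
  possible at all; an unstructured panel (`fst=0`) has a near-identity GRM
  and is retained for Hardy–Weinberg diagnostics.
* **Phenotypes.** Additive genetic values from `n_qtl` random markers,
  rescaled so the realized genetic variance equals the spec exactly.
  Genotype-by-year and genotype-by-nitrogen deviations are themselves
  marker-based draws (their own QTL effects per level, scaled to the spec
  variance): interaction variance is genetic variance, so G×E deviations
  carry kinship structure — the property the I⊗K kernels exploit and the
  sparse-testing design depends on. An i.i.d. alternative
  (`structured_gxe=False`) exists for variance-accounting tests. Block and
  residual effects are i.i.d. normal. All generated components are returned
  as truth for recovery tests.
* **Spectra.** Genotype curves are low-rank combinations of marker-driven
  latent factors (rank 20 by default; factor scores keep their natural
  covariance ∝ K, so the true spectral similarity is a noisy proxy of the
  GRM). Factor loadings are smooth curves with a 40 nm length-scale —
  absorption-feature width, so derivatives preserve them. A configurable
  share (30 % by default) of the genotypic spectral variance is
  environment-specific (each environment re-expresses the factor space),
  making each environment's HRM a partial view of the shared structure —
  the mechanism by which pooling NIRS environments improves phenomic
  prediction. Environment shifts are smooth additive baselines (100 nm
  length-scale); plot noise is 90 % smooth scattering-like baselines
  (200 nm) and 10 % white, which is exactly why derivative preprocessing
  helps. The genetic scale per wavelength is calibrated so the plug-in
  wavelength heritability matches `target_h2_profile` at the design's
  replicate count.
* **Seeding.** One master seed; each operation derives its own stream from
  `(seed, fixed op code)`, so outputs are bit-reproducible per operation.

### What the generator does not emulate

Linkage disequilibrium and family pedigrees (relatedness is purely
admixture-driven), genotyping error and missingness patterns, chemical
interpretability of spectra (factors are abstract, not constituent spectra),
spatial field trends, and trait-specific spectral signatures (the trait QTL
and spectral factors share only the marker space, not chosen loci). Passing
tests therefore demonstrate correctness of the estimators and the *direction*
of the method's behaviour under the stated structure, not field-data effect
sizes.

## Bundled experiments

`phenogp.experiments` packages two paired contrasts at desk scale
(100 genotypes, 800 markers, 300 wavelengths at 5 nm — a scaled-down version
of the 190 × 38k × 1,500 study; spectra variance sharing `share_window=3`;
fast chains):

* **Sparse testing** — predictive ability for a held-out half of a target
  environment when 0 % vs 50 % of that environment's genotypes train, paired
  on the same validation half (grain-yield-like trait, G×E-rich).
* **Environment scaling** — PA with 1, 2 or 3 training environments
  (single-environment = five-fold CV; multi-environment = 50 % target
  inclusion), for genomic, phenomic and combined kernels, pooled over
  rotated folds. Pooled fold predictions are centered per fit before
  correlating (fits differ in intercept; rescaling is deliberately avoided
  since it would inflate noise in strongly shrunken folds).

In this synthetic world the sparse-testing gain and the 2→3-environment
plateau reproduce the expected directions in the majority of panels. The
phenomic model's *absolute* 1→2-environment gain, however, generally does
not exceed the genomic model's: with admixture-only relatedness at n = 100,
single-environment genomic PA (~0.3) sits far below its own
cross-environment transfer ceiling (~0.75), so adding a second environment
benefits the genomic model hugely — whereas the classic pattern arises
when single-environment genomic PA is already near that ceiling, a property
of strongly related real panels that this generator does not produce. The
phenomic model does converge to the genomic one by three environments. This
limitation is inherent to the panel model, not to the estimators, and is
left visible rather than worked around.

## Degenerate inputs and numerical conventions

Constant responses give all-zero variances; zero-variance wavelengths give
zero BLUPs and H² = 0 (logged); undefined correlations (constant vectors,
< 3 pairs) are NaN with warnings, never silently dropped; singular
mixed-model equations receive a 1e-8 ridge with a warning; REML
non-convergence is flagged on the result. All file formats are plain text
(CSV/VCF/JSON/YAML), UTF-8, with genotype identifiers treated as opaque
strings; the pipeline writes a manifest with per-stage output checksums so
reruns can verify and skip completed stages.
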