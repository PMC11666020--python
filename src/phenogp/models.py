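"""Single- and multi-environment kernel prediction models.

Implements the G-BLUP family used for genomic (GP), phenomic (PP) and combined
(GP+PP) prediction:

* SM  - single-environment model, y = mu + u + e with u ~ N(0, s2 K).
* MM  - multi-environment main-effect model: environment fixed effects plus
  main genetic effects with covariance J (x) K over the stacked
  (genotype, environment) index - a uniform genetic effect across environments.
* MDs - MM plus block-diagonal I (x) K genotype-by-environment deviations
  sharing one variance per kernel family.

K is a genomic relationship matrix; phenomic terms use one hyperspectral
relationship matrix H_d per available NIRS environment d (each contributing
its own main - and under MDs its own GxE - random effect).

Fitting is by Gibbs sampling in each kernel's eigenbasis with
scaled-inverse-chi-squared variance priors and data augmentation for masked
responses; ``solve_blup`` provides the closed-form mixed-model-equation
solution at fixed variances (the sampler's deterministic oracle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import Kinship

__all__ = [
    "KernelSet",
    "ChainParams",
    "FitResult",
    "BlupSolution",
    "build_kernels",
    "fit_gibbs",
    "solve_blup",
    "predict",
]

MODELS = ("SM", "MM", "MDs")
INFOS = ("GP", "PP", "GP+PP")

#: kernel eigenvalues below this fraction of the maximum are truncated
EIG_TRUNC = 1e-10


@dataclass
class KernelSet:
    """Stacked multi-environment design: fixed effects + random-effect kernels."""

    index: pd.DataFrame                      # columns genotype, env (row order = stack order)
    X: np.ndarray                            # fixed design (intercept + env indicators)
    fixed_names: list[str]
    kernels: list[tuple[str, np.ndarray, str]]   # (label, matrix over stack, family)

    def __post_init__(self):
        n = len(self.index)
        labels = [lab for lab, _, _ in self.kernels]
        if len(set(labels)) != len(labels):
            raise ValueError("kernel labels must be unique")
        for lab, K, _ in self.kernels:
            if K.shape != (n, n):
                raise ValueError(f"kernel {lab} is not square on the stacked index")
            if np.max(np.abs(K - K.T)) > 1e-8:
                raise ValueError(f"kernel {lab} is not symmetric")

    @property
    def n(self) -> int:
        return len(self.index)


@dataclass
class ChainParams:
    """Gibbs chain settings; the printed defaults are the 'paper' preset."""

    burn_in: int = 10_000
    n_iter: int = 70_000
    thin: int = 10
    seed: int = 0
    prior_df: float = 5.0
    prior_r2: float = 0.5
    fixed_variances: dict | None = None      # label -> value (+ "residual"); skips updates

    def __post_init__(self):
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def paper(cls, seed: int = 0, **kw) -> "ChainParams":
        return cls(burn_in=10_000, n_iter=70_000, thin=10, seed=seed, **kw)

    @classmethod
    def fast(cls, seed: int = 0, **kw) -> "ChainParams":
        """Short chain for desk-scale work and tests."""
        return cls(burn_in=500, n_iter=3_000, thin=5, seed=seed, **kw)


@dataclass
class FitResult:
    kernels: KernelSet
    mask: np.ndarray                          # True where the response was hidden
    beta_mean: np.ndarray
    variance_mean: dict[str, float]
    variance_sd: dict[str, float]
    effects_mean: dict[str, np.ndarray]       # posterior-mean u_k on the stack
    fitted_mean: np.ndarray                   # posterior-mean linear predictor
    n_retained: int
    ess: dict[str, float]
    chain: ChainParams
    fitted_draws_masked: np.ndarray | None = None   # retained x n_masked draws

    def prediction_mc_se(self) -> np.ndarray:
        """Monte-Carlo standard error of each masked prediction, ESS-adjusted."""
        D = self.fitted_draws_masked
        ess = np.array([max(_ess(D[:, j]), 1.0) for j in range(D.shape[1])])
        return D.std(axis=0) / np.sqrt(ess)

    @property
    def predictions(self) -> pd.DataFrame:
        out = self.kernels.index.copy()
        out["predicted"] = self.fitted_mean
        return out[self.mask].reset_index(drop=True)


@dataclass
class BlupSolution:
    beta: np.ndarray
    effects: dict[str, np.ndarray]
    fitted: np.ndarray


# ---------------------------------------------------------------------------
# kernel construction
# ---------------------------------------------------------------------------

def _restrict(K: Kinship, genos: pd.Series) -> np.ndarray:
    pos = {g: i for i, g in enumerate(K.ids)}
    missing = sorted(set(genos) - set(pos))
    if missing:
        raise KeyError(f"kinship lacks genotypes: {', '.join(map(str, missing[:5]))}")
    idx = genos.map(pos).to_numpy()
    return idx


def build_kernels(
    model: str,
    info: str,
    grm: Kinship | None = None,
    hrms: dict[str, Kinship] | None = None,
    index: pd.DataFrame | None = None,
    observed=None,
) -> KernelSet:
    """Assemble fixed design and covariance kernels on a stacked (genotype, env) index.

    ``hrms`` maps NIRS-environment label -> HRM; under PP each contributes one
    main random effect (J (x) H_d structure) and, for MDs, one block-diagonal
    GxE effect (I (x) H_d).  When ``observed`` (boolean per stacked row) is
    given, environments with no observed response get no fixed-effect
    indicator: their level is aliased to the reference, which leaves
    correlation-based predictive ability untouched while keeping the design
    estimable in fully-masked-environment scenarios.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if info not in INFOS:
        raise ValueError(f"info must be one of {INFOS}")
    if index is None or not {"genotype", "env"} <= set(index.columns):
        raise ValueError("index must be a DataFrame with genotype and env columns")
    index = index.reset_index(drop=True)
    envs = list(dict.fromkeys(index["env"]))
    if model == "SM" and len(envs) != 1:
        raise ValueError("SM requires exactly one environment in the index")
    if info in ("GP", "GP+PP") and grm is None:
        raise ValueError("genomic info requested but no GRM given")
    if info in ("PP", "GP+PP") and not hrms:
        raise ValueError("phenomic info requested but no HRMs given")

    n = len(index)
    # fixed design: intercept + environment indicators (drop-first coding)
    cols = [np.ones(n)]
    names = ["intercept"]
    if model != "SM":
        if observed is not None:
            observed = np.asarray(observed, dtype=bool)
            est_envs = [e for e in envs if (index["env"].to_numpy() == e)[observed].any()]
        else:
            est_envs = envs
        for e in est_envs[1:]:
            cols.append((index["env"] == e).to_numpy(dtype=float))
            names.append(f"env[{e}]")
    X = np.column_stack(cols)

    same_env = (index["env"].to_numpy()[:, None] == index["env"].to_numpy()[None, :])
    kernels: list[tuple[str, np.ndarray, str]] = []

    def main_and_gxe(label: str, K: Kinship, family: str):
        idx = _restrict(K, index["genotype"])
        Kg = K.matrix[np.ix_(idx, idx)]
        kernels.append((f"{label}_main", Kg, f"main_{family}"))
        if model == "MDs":
            kernels.append((f"{label}_gxe", Kg * same_env, f"gxe_{family}"))

    if info in ("GP", "GP+PP"):
        main_and_gxe("g", grm, "genomic")
    if info in ("PP", "GP+PP"):
        for d, H in hrms.items():
            main_and_gxe(f"p_{d}", H, f"phenomic_env_{d}")

    return KernelSet(index=index, X=X, fixed_names=names, kernels=kernels)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _eigendecompose(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(K)
    cut = EIG_TRUNC * max(vals.max(), 0.0)
    keep = vals > cut
    if vals.min() < -1e-6 * max(vals.max(), 1.0):
        raise ValueError(f"kernel has a substantially negative eigenvalue ({vals.min():.3e})")
    if not keep.any():
        raise ValueError("kernel is numerically zero")
    return vals[keep], vecs[:, keep]


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence autocorrelation rule."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, n // 2):
        pair = acf[2 * k - 1] + acf[2 * k] if 2 * k < n else 0.0
        if pair <= 0:
            break
        s += pair
    return float(n / (1.0 + 2.0 * s))


def fit_gibbs(
    y,
    mask,
    kernels: KernelSet,
    chain: ChainParams,
) -> FitResult:
    """Gibbs sampler for the kernel mixed model with masked-response augmentation.

    Fixed effects get a flat prior; each kernel's random effect is sampled in
    its eigenbasis (coefficients independent given the variances); variances
    get scaled-inverse-chi-squared priors with ``prior_df`` degrees of freedom
    and scales that split ``prior_r2`` of the observed-response variance evenly
    across the genetic kernels, the remainder to the residual.  Masked
    responses are redrawn each sweep from their conditional normal.
    """
    y = np.asarray(y, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool)
    n = kernels.n
    if y.size != n or mask.size != n:
        raise ValueError("y/mask length must match the stacked index")
    if mask.all():
        raise ValueError("all responses masked; nothing to train on")
    if np.linalg.matrix_rank(kernels.X[~mask]) < kernels.X.shape[1]:
        raise ValueError(
            "fixed effects inestimable from the observed rows; rebuild the "
            "kernel set with observed= so fully-masked environments are aliased"
        )
    if np.isnan(y[~mask]).any():
        raise ValueError("observed responses contain NaN")

    rng = np.random.default_rng(chain.seed)
    X = kernels.X
    p = X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    cX = np.linalg.cholesky(XtX_inv)

    # sample on unit-mean-diagonal kernels (well-posed priors whatever the raw
    # kernel scale, e.g. tiny derivative-spectra HRMs); variances are reported
    # back on the raw-kernel scale, so effects and predictions are unchanged
    eig = []
    kscale = {}
    for lab, K, _ in kernels.kernels:
        c = float(np.trace(K)) / K.shape[0]
        if c <= 0:
            raise ValueError(f"kernel {lab} has non-positive mean diagonal")
        d, U = _eigendecompose(K / c)
        eig.append((lab, d, U))
        kscale[lab] = c
    nk = len(eig)
    labels = [lab for lab, _, _ in eig]

    vy = float(np.var(y[~mask]))
    vy = vy if vy > 0 else 1.0
    df0 = chain.prior_df
    fixed = chain.fixed_variances or {}
    # prior scales: mode approximately at the targeted variance share
    share = chain.prior_r2 / max(nk, 1)
    S0 = {lab: vy * share * (df0 + 2.0) / df0 for lab in labels}
    S0["residual"] = vy * (1.0 - chain.prior_r2) * (df0 + 2.0) / df0

    # state (variances on the normalized-kernel scale internally)
    beta = XtX_inv @ X.T @ np.nan_to_num(y)
    alpha = [np.zeros(d.size) for _, d, _ in eig]
    u = [np.zeros(n) for _ in range(nk)]
    s2 = {lab: fixed[lab] * kscale[lab] if lab in fixed else vy * share for lab in labels}
    s2["residual"] = fixed.get("residual", vy * (1.0 - chain.prior_r2))
    yfull = np.where(mask, float(np.nanmean(y[~mask])), y)

    retained = 0
    beta_sum = np.zeros(p)
    eta_sum = np.zeros(n)
    u_sum = [np.zeros(n) for _ in range(nk)]
    var_draws = {lab: [] for lab in list(labels) + ["residual"]}
    masked_draws = []

    for it in range(chain.n_iter):
        # fixed effects
        resid = yfull - sum(u)
        bhat = XtX_inv @ (X.T @ resid)
        beta = bhat + np.sqrt(s2["residual"]) * (cX @ rng.standard_normal(p))
        eta_fixed = X @ beta

        # kernel effects in their eigenbases
        for k, (lab, d, U) in enumerate(eig):
            r = yfull - eta_fixed - (sum(u) - u[k])
            c = U.T @ r
            prec = 1.0 / s2["residual"] + 1.0 / (s2[lab] * d)
            mean = c / (s2["residual"] * prec)
            alpha[k] = mean + rng.standard_normal(d.size) / np.sqrt(prec)
            u[k] = U @ alpha[k]

        # variances
        for k, (lab, d, _) in enumerate(eig):
            if lab in fixed:
                continue
            ss = float(np.sum(alpha[k] ** 2 / d)) + df0 * S0[lab]
            s2[lab] = ss / rng.chisquare(df0 + d.size)
        if "residual" not in fixed:
            e = yfull - eta_fixed - sum(u)
            ss = float(e @ e) + df0 * S0["residual"]
            s2["residual"] = ss / rng.chisquare(df0 + n)

        # data augmentation at masked positions
        eta = eta_fixed + sum(u)
        if mask.any():
            yfull[mask] = eta[mask] + np.sqrt(s2["residual"]) * rng.standard_normal(int(mask.sum()))

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            retained += 1
            beta_sum += beta
            eta_sum += eta
            for k in range(nk):
                u_sum[k] += u[k]
            for lab in var_draws:
                var_draws[lab].append(s2[lab])
            masked_draws.append(eta[mask].copy())

    expected = (chain.n_iter - chain.burn_in + chain.thin - 1) // chain.thin
    assert retained == expected, "retained-sample accounting error"
    var_arr = {
        lab: np.asarray(v) / kscale.get(lab, 1.0) for lab, v in var_draws.items()
    }
    return FitResult(
        kernels=kernels,
        mask=mask,
        beta_mean=beta_sum / retained,
        variance_mean={lab: float(v.mean()) for lab, v in var_arr.items()},
        variance_sd={lab: float(v.std()) for lab, v in var_arr.items()},
        effects_mean={lab: u_sum[k] / retained for k, lab in enumerate(labels)},
        fitted_mean=eta_sum / retained,
        n_retained=retained,
        ess={lab: _ess(v) for lab, v in var_arr.items()},
        chain=chain,
        fitted_draws_masked=np.asarray(masked_draws),
    )


# ---------------------------------------------------------------------------
# closed-form oracle
# ---------------------------------------------------------------------------

def solve_blup(
    y,
    mask,
    kernels: KernelSet,
    variances: dict[str, float],
) -> BlupSolution:
    """Mixed-model-equation solution at fixed variances.

    Solves the penalized least-squares system for fixed effects and the
    eigenbasis coefficients of every kernel on the observed rows, then
    reconstructs effects (hence predictions) on the full stacked index.
    """
    y = np.asarray(y, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    obs = ~mask
    labels = [lab for lab, _, _ in kernels.kernels]
    for lab in labels + ["residual"]:
        if variances.get(lab, 0.0) <= 0:
            raise ValueError(f"variance for {lab!r} must be strictly positive")

    X = kernels.X
    eig = [(lab, *_eigendecompose(K)) for lab, K, _ in kernels.kernels]
    blocks = [X[obs]] + [U[obs] for _, _, U in eig]
    W = np.column_stack(blocks)
    s2e = variances["residual"]
    sizes = [X.shape[1]] + [d.size for _, d, _ in eig]
    penalty = np.concatenate(
        [np.zeros(X.shape[1])]
        + [s2e / (variances[lab] * d) for lab, d, _ in eig]
    )
    A = W.T @ W + np.diag(penalty)
    b = W.T @ y[obs]
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        warnings.warn("singular mixed-model equations; adding 1e-8 ridge jitter")
        A[np.diag_indices_from(A)] += 1e-8
        sol = np.linalg.solve(A, b)

    beta = sol[: X.shape[1]]
    effects = {}
    fitted = X @ beta
    off = X.shape[1]
    for (lab, d, U), m in zip(eig, sizes[1:]):
        a = sol[off: off + m]
        off += m
        effects[lab] = U @ a
        fitted = fitted + effects[lab]
    return BlupSolution(beta=beta, effects=effects, fitted=fitted)


def predict(fit: FitResult, targets: list[tuple]) -> pd.DataFrame:
    """Posterior-mean predictions at (genotype, environment) targets."""
    idx = fit.kernels.index
    key = pd.MultiIndex.from_frame(idx[["genotype", "env"]])
    lookup = pd.Series(fit.fitted_mean, index=key)
    rows = []
    for g, e in targets:
        if (g, e) not in lookup.index:
            raise KeyError(f"target ({g}, {e}) not in the stacked index")
        rows.append(dict(genotype=g, env=e, predicted=float(lookup[(g, e)])))
    return pd.DataFrame(rows, columns=["genotype", "env", "predicted"])
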