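"""NIRS spectra preprocessing and per-wavelength genotype BLUPs.

Preprocessing transforms (row-wise over each plot spectrum): Savitzky-Golay
smoothing, standard normal variate (SNV), detrend (SNV + 2nd-order polynomial
baseline removal) and first/second derivatives of SNV-normalized spectra.
The default pipeline retained downstream is the second derivative (der2).

The per-environment, per-wavelength mixed model
``reflectance = mu + block(rep) + geno + e`` (block and genotype random) yields
the genotype BLUP matrix Sp* (genotypes x wavelengths) and the wavelength
heritability H2 = s2_geno / (s2_geno + s2_e / N_R).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .reml import fit_reml
from .simulate import SpectraSet

__all__ = [
    "SpectralBlups",
    "preprocess",
    "snv",
    "spectra_blups",
    "wavelength_heritability",
    "DEFAULT_SG_WINDOW",
    "DEFAULT_SG_ORDER",
]

# Savitzky-Golay defaults: wide enough to suppress 1 nm-grid noise while
# preserving absorption-band shape; both are overridable per call.
DEFAULT_SG_WINDOW = 37
DEFAULT_SG_ORDER = 2


@dataclass
class SpectralBlups:
    """Per-environment spectral genotype BLUPs and variance components."""

    environment: str
    sp: pd.DataFrame                 # genotypes x wavelength columns (BLUPs)
    var_geno: np.ndarray             # per wavelength
    var_resid: np.ndarray
    n_rep: float                     # harmonic mean replicates per genotype
    wavelength_grid: np.ndarray
    preprocessing_tag: list = field(default_factory=list)

    @property
    def h2(self) -> np.ndarray:
        return wavelength_heritability(self)

    @property
    def n_wavelengths(self) -> int:
        return self.sp.shape[1]


def snv(M: np.ndarray) -> np.ndarray:
    """Standard normal variate: center and unit-scale each row (spectrum)."""
    M = np.asarray(M, dtype=float)
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (M - mu) / sd


def _detrend(M: np.ndarray, grid: np.ndarray, order: int = 2) -> np.ndarray:
    """SNV followed by removal of a per-row polynomial baseline in wavelength."""
    M = snv(M)
    x = (grid - grid.mean()) / (grid.std() if grid.std() > 0 else 1.0)
    B = np.vander(x, order + 1)                    # columns x^order .. 1
    coef, *_ = np.linalg.lstsq(B, M.T, rcond=None)
    return M - (B @ coef).T


def preprocess(spectra: SpectraSet, method: str, window: int = DEFAULT_SG_WINDOW,
               polyorder: int = DEFAULT_SG_ORDER) -> SpectraSet:
    """Apply one preprocessing transform row-wise; derivatives act on SNV-normalized rows.

    Derivative output grids are trimmed by half the filter window at each edge
    (never padded), so downstream wavelength counts L reflect retained points.
    """
    grid = spectra.wavelength_grid
    M = spectra.matrix()
    if method in ("der1", "der2", "smooth"):
        steps = np.diff(grid)
        if steps.size and not np.allclose(steps, steps[0]):
            raise ValueError("derivative/smoothing methods require an evenly spaced grid")
        if window > M.shape[1]:
            raise ValueError(f"filter window {window} exceeds spectrum length {M.shape[1]}")
        if window % 2 == 0:
            raise ValueError("filter window must be odd")

    new_grid = grid
    if method == "snv" or method == "normalize":
        out = snv(M)
    elif method == "detrend":
        out = _detrend(M, grid)
    elif method == "smooth":
        out = savgol_filter(M, window, polyorder, axis=1)
    elif method in ("der1", "der2"):
        deriv = 1 if method == "der1" else 2
        delta = float(grid[1] - grid[0]) if grid.size > 1 else 1.0
        out = savgol_filter(snv(M), window, max(polyorder, deriv), deriv=deriv,
                            delta=delta, axis=1)
        half = window // 2
        out = out[:, half:M.shape[1] - half]
        new_grid = grid[half:grid.size - half]
    else:
        raise ValueError(f"unknown preprocessing method {method!r}")

    meta_cols = [c for c in spectra.data.columns if not c.startswith("wl_")]
    cols = [f"wl_{int(round(w))}" for w in new_grid]
    data = pd.concat(
        [spectra.data[meta_cols].reset_index(drop=True), pd.DataFrame(out, columns=cols)],
        axis=1,
    )
    tag = list(spectra.preprocessing_tag) + [
        {"method": method, "window": window, "polyorder": polyorder}
        if method in ("smooth", "der1", "der2")
        else {"method": method}
    ]
    return SpectraSet(data=data, wavelength_grid=np.asarray(new_grid), preprocessing_tag=tag)


def _harmonic_mean(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    return counts.size / np.sum(1.0 / counts) if counts.size else np.nan


def spectra_blups(spectra: SpectraSet, environment: str,
                  share_window: int = 1) -> SpectralBlups:
    """Fit the wavelength-wise mixed model within one environment.

    Each wavelength is fitted independently (random genotype and block-in-rep,
    fixed intercept) with the shared REML engine; a wavelength with zero
    variance yields all-zero BLUPs and H2 = 0.  With ``share_window`` > 1,
    variance components are estimated by REML on every ``share_window``-th
    wavelength and shared with the neighbours (whose BLUPs are then a single
    generalized-least-squares solve); adjacent wavelengths have near-identical
    variance ratios, so this trades little accuracy for a large speed-up.
    """
    df = spectra.data[spectra.data["env"] == environment].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no spectra for environment {environment!r}")
    if "scan" in df.columns:
        # technical scans are averaged to plot level before modelling
        keys = [c for c in ("genotype", "env", "rep", "block") if c in df.columns]
        df = df.groupby(keys, as_index=False).mean(numeric_only=True)

    wl_cols = spectra.wl_columns
    M = df[wl_cols].to_numpy(dtype=float)
    genos = sorted(df["genotype"].unique())
    n_g = len(genos)
    X = np.ones((len(df), 1))
    labels = {
        "geno": df["genotype"].to_numpy(),
        "block": ("r" + df["rep"].astype(str) + "/b" + df["block"].astype(str)).to_numpy(),
    }
    single_block = len(set(labels["block"])) < 2
    if single_block:
        labels.pop("block")

    codes = {k: np.unique(v, return_inverse=True) for k, v in labels.items()}
    G = {k: (c[1][:, None] == c[1][None, :]).astype(float) for k, c in codes.items()}
    geno_levels, geno_codes = codes["geno"]
    Zg = np.zeros((len(df), geno_levels.size))
    Zg[np.arange(len(df)), geno_codes] = 1.0
    pos = {g: k for k, g in enumerate(geno_levels)}
    row_of = np.array([pos[g] for g in genos])

    def blup_at(y, variances):
        V = np.eye(len(df)) * max(variances["residual"], 1e-12)
        for k in G:
            if variances.get(k, 0.0) > 0:
                V += variances[k] * G[k]
        Vi = np.linalg.inv(V)
        XtViX_inv = np.linalg.inv(X.T @ Vi @ X)
        beta = XtViX_inv @ X.T @ Vi @ y
        return variances.get("geno", 0.0) * (Zg.T @ (Vi @ (y - X @ beta)))

    sp = np.zeros((n_g, len(wl_cols)))
    vg = np.zeros(len(wl_cols))
    ve = np.zeros(len(wl_cols))
    shared = None
    for j in range(len(wl_cols)):
        y = M[:, j]
        if np.std(y) == 0:
            continue
        if share_window <= 1 or j % share_window == 0 or shared is None:
            res = fit_reml(y, X, labels)
            shared = res.variances
            u = res.blups["geno"]
        else:
            # reuse the latest variance ratios, rescaled to this wavelength
            sc = np.var(y) / max(sum(shared.values()), 1e-300)
            u = blup_at(y, {k: v * sc for k, v in shared.items()})
            shared = {**shared}  # keep ratios; store rescaled for reporting
            shared_scaled = {k: v * sc for k, v in shared.items()}
            sp[row_of, j] = u
            vg[j] = shared_scaled["geno"]
            ve[j] = shared_scaled["residual"]
            continue
        sp[row_of, j] = u
        vg[j] = shared["geno"]
        ve[j] = shared["residual"]

    n_rep = _harmonic_mean(df.groupby("genotype").size().to_numpy())
    return SpectralBlups(
        environment=environment,
        sp=pd.DataFrame(sp, index=genos, columns=wl_cols),
        var_geno=vg,
        var_resid=ve,
        n_rep=n_rep,
        wavelength_grid=spectra.wavelength_grid.copy(),
        preprocessing_tag=list(spectra.preprocessing_tag),
    )


def wavelength_heritability(blups: SpectralBlups) -> np.ndarray:
    """H2 = s2_geno / (s2_geno + s2_e / N_R) per wavelength; 0 where undefined."""
    denom = blups.var_geno + blups.var_resid / blups.n_rep
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(denom > 0, blups.var_geno / np.where(denom > 0, denom, 1.0), 0.0)
    n_zero = int(np.sum(denom <= 0))
    if n_zero:
        warnings.warn(f"{n_zero} wavelengths with zero total variance; H2 set to 0")
    return h2
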