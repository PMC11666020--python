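"""Restricted maximum likelihood for variance-component mixed models.

Fits y = X b + sum_k Z_k u_k + e with u_k ~ N(0, s2_k I) i.i.d. per level of a
grouping factor, and e ~ N(0, s2_e I).  This is the model family behind the
plot-level variance decomposition, the per-environment BLUE model and the
per-wavelength spectral BLUP model, so one engine serves all three.

Algorithm: average-information (AI) REML with EM fallback steps when the AI
update leaves the parameter space, and projection of variances onto [0, inf).
Dense linear algebra throughout; trial sizes here are a few thousand plots at
most, for which explicit V inverses are cheap and far more robust than sparse
iterative schemes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = ["RemlResult", "fit_reml", "build_groups"]

#: relative-change convergence threshold on all variance components
REML_TOL = 1e-8
REML_MAX_ITER = 200


@dataclass
class RemlResult:
    """Converged (or last-iterate) REML fit."""

    variances: dict[str, float]            # per random factor + "residual"
    beta: np.ndarray                       # GLS fixed-effect estimates
    beta_se: np.ndarray
    fixed_names: list[str]
    blups: dict[str, np.ndarray]           # per factor, aligned with `levels`
    levels: dict[str, np.ndarray]          # level labels per factor
    converged: bool
    n_iter: int
    loglik: float
    scale: float = 1.0                     # internal y-scaling used during the fit
    extra: dict = field(default_factory=dict)

    def variance_fractions(self) -> dict[str, float]:
        tot = sum(self.variances.values())
        if tot <= 0:
            return {k: 0.0 for k in self.variances}
        return {k: v / tot for k, v in self.variances.items()}


def build_groups(labels) -> tuple[np.ndarray, np.ndarray]:
    """Integer-code a label vector; returns (codes, unique levels in order of appearance)."""
    arr = np.asarray(labels)
    levels, codes = np.unique(arr, return_inverse=True)
    return codes, levels


def _incidence(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def fit_reml(
    y,
    X,
    random_labels: dict[str, np.ndarray],
    tol: float = REML_TOL,
    max_iter: int = REML_MAX_ITER,
) -> RemlResult:
    """AI-REML fit of a scalar variance-component model.

    Parameters
    ----------
    y : (n,) response vector (no missing values).
    X : (n, p) fixed-effect design, full column rank.
    random_labels : mapping factor name -> length-n label vector; each factor
        contributes one variance component with i.i.d. effects per level.

    Notes
    -----
    Variances are estimated on a rescaled response (unit total variance) and
    scaled back, so convergence behaviour is scale-free.  A factor estimated at
    the zero boundary stays in the model (score steps may revive it).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X and y have incompatible shapes")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    names = list(random_labels)
    codes = {}
    levels = {}
    for k in names:
        c, lev = build_groups(random_labels[k])
        if lev.size < 2:
            raise ValueError(f"random factor {k!r} has a single level; variance inestimable")
        codes[k] = c
        levels[k] = lev

    sy = float(np.std(y))
    if sy == 0.0:
        # degenerate data: all variances zero, beta from OLS
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return RemlResult(
            variances={**{k: 0.0 for k in names}, "residual": 0.0},
            beta=beta,
            beta_se=np.zeros(X.shape[1]),
            fixed_names=[f"x{j}" for j in range(X.shape[1])],
            blups={k: np.zeros(levels[k].size) for k in names},
            levels=levels,
            converged=True,
            n_iter=0,
            loglik=0.0,
        )
    ys = y / sy

    # relationship matrices G_k = Z_k Z_k' (dense; n is modest by design)
    G = {k: (codes[k][:, None] == codes[k][None, :]).astype(float) for k in names}
    comp = names + ["residual"]
    p0 = 1.0 / (len(comp) + 1)
    theta = {k: p0 for k in comp}
    theta["residual"] = max(theta["residual"], 0.05)

    n_par = len(comp)
    q = {k: levels[k].size for k in names}
    q["residual"] = n

    def _loglik(th: np.ndarray) -> float:
        V = np.eye(n) * th[-1]
        for i, k in enumerate(names):
            if th[i] > 0:
                V += th[i] * G[k]
        try:
            cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return -np.inf
        Vi_y = linalg.cho_solve(cf, ys)
        Vi_X = linalg.cho_solve(cf, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        yPy = float(ys @ Vi_y - (X.T @ Vi_y) @ beta)
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        _, logdetX = np.linalg.slogdet(XtViX)
        return -0.5 * (logdetV + logdetX + yPy)

    converged = False
    it = 0
    loglik = _loglik(np.array([theta[k] for k in comp]))
    for it in range(1, max_iter + 1):
        V = np.eye(n) * theta["residual"]
        for k in names:
            if theta[k] > 0:
                V += theta[k] * G[k]
        try:
            cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            V[np.diag_indices_from(V)] += 1e-10
            cf = linalg.cho_factor(V, lower=True)
        Vinv = linalg.cho_solve(cf, np.eye(n))
        VinvX = Vinv @ X
        XtVinvX = X.T @ VinvX
        XtVinvX_inv = np.linalg.inv(XtVinvX)
        P = Vinv - VinvX @ XtVinvX_inv @ VinvX.T
        Py = P @ ys

        GPy = {k: G[k] @ Py for k in names}
        GPy["residual"] = Py

        trPG = {}
        score = np.empty(n_par)
        quad = {}
        for i, k in enumerate(comp):
            trPG[k] = float(np.sum(P * G[k])) if k != "residual" else float(np.trace(P))
            quad[k] = float(Py @ GPy[k])
            score[i] = -0.5 * (trPG[k] - quad[k])

        AI = np.empty((n_par, n_par))
        PGPy = {k: P @ GPy[k] for k in comp}
        for i, ki in enumerate(comp):
            for j, kj in enumerate(comp):
                AI[i, j] = AI[j, i] if j < i else 0.5 * float(GPy[ki] @ PGPy[kj])

        old = np.array([theta[k] for k in comp])

        # components pinned at zero with a negative gradient stay out this round
        free = ~((old[:-1] == 0.0) & (score[:-1] < 0))
        free = np.append(free, True)

        try:
            delta = np.zeros(n_par)
            idx = np.flatnonzero(free)
            delta[idx] = np.linalg.solve(
                AI[np.ix_(idx, idx)] + 1e-10 * np.eye(idx.size), score[idx]
            )
        except np.linalg.LinAlgError:
            delta = np.where(free, score / max(np.diag(AI).max(), 1.0), 0.0)

        # AI step with projection, guarded by the REML log-likelihood;
        # fall back to a guaranteed-ascent EM step if halving fails
        new = None
        step = 1.0
        for _ in range(12):
            cand = np.maximum(old + step * delta, 0.0)
            cand[-1] = max(cand[-1], 1e-12)
            ll = _loglik(cand)
            if ll >= loglik - 1e-10:
                new, loglik = cand, ll
                break
            step *= 0.5
        if new is None:
            cand = old.copy()
            for i, k in enumerate(comp):
                if old[i] > 0:
                    cand[i] = old[i] + (old[i] ** 2 / q[k]) * (quad[k] - trPG[k])
            cand = np.maximum(cand, 0.0)
            cand[-1] = max(cand[-1], 1e-12)
            new = cand
            loglik = _loglik(new)

        denom = np.maximum(np.abs(old), 1e-6)
        rel = np.max(np.abs(new - old) / denom)
        for i, k in enumerate(comp):
            theta[k] = float(new[i])
        if rel < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"REML did not converge in {max_iter} iterations (last rel change {rel:.2e}); "
            "returning last iterate",
            RuntimeWarning,
        )

    # final GLS solve and BLUPs at the converged variances
    V = np.eye(n) * theta["residual"]
    for k in names:
        V += theta[k] * G[k]
    V[np.diag_indices_from(V)] += 1e-12
    cf = linalg.cho_factor(V, lower=True)
    Vinv = linalg.cho_solve(cf, np.eye(n))
    XtVinvX_inv = np.linalg.inv(X.T @ Vinv @ X)
    beta_s = XtVinvX_inv @ X.T @ Vinv @ ys
    resid = ys - X @ beta_s
    Vinv_resid = Vinv @ resid
    blups = {}
    for k in names:
        Z = _incidence(codes[k], levels[k].size)
        blups[k] = theta[k] * (Z.T @ Vinv_resid) * sy
    beta = beta_s * sy
    beta_se = np.sqrt(np.maximum(np.diag(XtVinvX_inv), 0.0)) * sy

    variances = {k: theta[k] * sy**2 for k in names}
    variances["residual"] = theta["residual"] * sy**2
    return RemlResult(
        variances=variances,
        beta=beta,
        beta_se=beta_se,
        fixed_names=[f"x{j}" for j in range(X.shape[1])],
        blups=blups,
        levels=levels,
        converged=converged,
        n_iter=it,
        loglik=loglik,
        scale=sy,
    )
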