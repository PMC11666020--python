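"""SNP quality control and genomic / hyperspectral relationship matrices.

The genomic relationship matrix (GRM) follows VanRaden's first method,
K = ZZ' / (2 * sum_j p_j (1 - p_j)) with Z the dosage matrix centered by twice
the observed allele frequency.  The hyperspectral relationship matrix (HRM) is
H = Sp* Sp*' / L over the per-environment spectral genotype BLUPs Sp* with L
retained wavelengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix
from .spectra import SpectralBlups

__all__ = ["Kinship", "FilterReport", "filter_snps", "grm_vanraden", "hrm", "align_kinships"]

#: eigenvalues below this raise; in (-PSD_TOL, 0) they are clipped to zero
PSD_TOL = 1e-8
SYM_TOL = 1e-10


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    n_fail_call_rate: int
    n_fail_het: int
    n_fail_maf: int
    n_het_calls_masked: int


@dataclass
class Kinship:
    """Square symmetric relationship matrix over an ordered genotype list."""

    matrix: np.ndarray
    ids: list[str]
    kind: str                               # genomic | hyperspectral | combined
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        K = np.asarray(self.matrix, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1] or K.shape[0] != len(self.ids):
            raise ValueError("kinship matrix shape does not match id list")
        asym = np.max(np.abs(K - K.T)) if K.size else 0.0
        if asym > SYM_TOL:
            raise ValueError(f"kinship matrix asymmetric (max |K-K'| = {asym:.2e})")
        K = 0.5 * (K + K.T)
        w = np.linalg.eigvalsh(K)
        if w.min() < -PSD_TOL * max(1.0, abs(w.max())):
            raise ValueError(f"kinship matrix not PSD (min eigenvalue {w.min():.3e})")
        if w.min() < 0:
            # repair tiny negative eigenvalues from floating-point round-off
            vals, vecs = np.linalg.eigh(K)
            K = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
            K = 0.5 * (K + K.T)
            warnings.warn(f"clipped {int(np.sum(w < 0))} tiny negative eigenvalues to 0")
        self.matrix = K

    @property
    def n(self) -> int:
        return len(self.ids)

    def dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def filter_snps(
    geno: GenotypeMatrix,
    max_missing: float = 0.20,
    max_het: float = 0.20,
    min_maf: float = 0.025,
    convert_het: bool = True,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Discard markers with call rate < 1 - max_missing, het rate > max_het or
    MAF < min_maf; then set remaining heterozygous calls to missing."""
    call = geno.call_rate()
    het = geno.het_rate()
    maf = geno.maf()
    fail_call = call < (1.0 - max_missing)
    fail_het = het > max_het
    fail_maf = maf < min_maf
    keep = ~(fail_call | fail_het | fail_maf)
    if not keep.any():
        raise ValueError("all markers removed by QC filters")
    out = geno.subset_markers(keep)
    n_masked = 0
    if convert_het:
        het_mask = out.dosages == 1
        n_masked = int(het_mask.sum())
        out.dosages[het_mask] = np.nan
    report = FilterReport(
        n_input=geno.n_markers,
        n_retained=out.n_markers,
        n_fail_call_rate=int(fail_call.sum()),
        n_fail_het=int(fail_het.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_het_calls_masked=n_masked,
    )
    return out, report


def grm_vanraden(geno: GenotypeMatrix) -> Kinship:
    """VanRaden GRM: K = ZZ' / (2 sum_j p_j(1-p_j)), Z column-centered by 2 p_j.

    Monomorphic markers contribute nothing and are excluded from the
    denominator.  Residual missing dosages are mean-imputed per marker with a
    warning (imputation proper is upstream of this package).
    """
    D = geno.dosages.astype(float).copy()
    miss = np.isnan(D)
    if miss.any():
        warnings.warn(
            f"{int(miss.sum())} missing dosages mean-imputed per marker before GRM"
        )
        col_mean = np.nanmean(D, axis=0)
        D[miss] = np.take(col_mean, np.where(miss)[1])
    p = D.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers monomorphic; GRM undefined")
    Z = D - 2.0 * p[None, :]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = (Z @ Z.T) / denom
    return Kinship(
        matrix=K,
        ids=list(geno.ids),
        kind="genomic",
        provenance={"n_markers": int(poly.sum()), "method": "vanraden"},
    )


def hrm(sp: SpectralBlups, scale_columns: bool = False) -> Kinship:
    """HRM: H = Sp* Sp*' / L from one environment's spectral BLUPs.

    ``scale_columns`` optionally unit-scales each wavelength's BLUP column
    first; off by default since the defining formula has no scaling.
    """
    S = sp.sp.to_numpy(dtype=float)
    L = S.shape[1]
    if L == 0:
        raise ValueError("no wavelengths in spectral BLUPs; HRM undefined")
    if scale_columns:
        sd = S.std(axis=0)
        S = S / np.where(sd > 0, sd, 1.0)
    H = (S @ S.T) / L
    return Kinship(
        matrix=H,
        ids=list(sp.sp.index),
        kind="hyperspectral",
        provenance={"environment": sp.environment, "n_wavelengths": int(L),
                    "scaled_columns": bool(scale_columns)},
    )


def align_kinships(matrices: list[Kinship], id_list: list[str]) -> list[Kinship]:
    """Subset and reorder every kinship to a common genotype order."""
    out = []
    for kin in matrices:
        pos = {g: i for i, g in enumerate(kin.ids)}
        missing = [g for g in id_list if g not in pos]
        if missing:
            raise KeyError(
                f"{kin.kind} kinship lacks genotypes: {', '.join(map(str, missing[:5]))}"
            )
        idx = np.array([pos[g] for g in id_list])
        out.append(
            Kinship(
                matrix=kin.matrix[np.ix_(idx, idx)],
                ids=list(id_list),
                kind=kin.kind,
                provenance=dict(kin.provenance),
            )
        )
    return out
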