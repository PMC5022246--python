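"""Relationship matrices: pedigree A, genomic G, and the ssGBLUP blend H.

Quality control of SNP genotypes (call rate, minor allele frequency,
Hardy-Weinberg chi-square), the numerator relationship matrix by the tabular
method with its sparse inverse by Henderson's rules, the genomic relationship
matrix of VanRaden's first method with observed allele frequencies, the
blended single-step inverse

    H^-1 = A^-1 + [0 0; 0 (alpha*G + beta*A22)^-1 - A22^-1],

and the linkage-disequilibrium summary Me = 1 / var(G - A22) over pairs
(the effective number of independently segregating chromosome segments).

The blending weights default to (alpha, beta) = (0.95, 2 - alpha) as used in
the analysis this package reimplements; the more common beta = 1 - alpha
convention is available via ``beta_convention="complement"``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import QCThresholds
from .simdata import GenotypeMatrix, Pedigree

__all__ = [
    "qc_filter",
    "build_A",
    "A_inverse",
    "subset_A",
    "build_G",
    "blend_H_inverse",
    "compute_Me",
    "var_offdiag",
    "GenomicArchitecture",
    "AllSNPsRemoved",
]


class AllSNPsRemoved(RuntimeError):
    """Raised when quality control removes every SNP."""


def _hwe_chisq(X: np.ndarray) -> np.ndarray:
    """1-df chi-square for deviation from Hardy-Weinberg genotype counts.

    Observed 0/1/2 counts are compared with n*(q^2, 2pq, p^2) at the observed
    allele frequency; missing calls are excluded per SNP.
    """
    chis = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        x = X[:, j]
        x = x[x != GenotypeMatrix.MISSING]
        n = x.size
        if n == 0:
            chis[j] = np.inf
            continue
        p = x.mean() / 2.0
        exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        obs = np.array([(x == 0).sum(), (x == 1).sum(), (x == 2).sum()], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
        chis[j] = terms.sum()
    return chis


def qc_filter(
    genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the three SNP filters in order call-rate, MAF, HWE.

    A SNP is removed if its call rate is below ``min_call_rate``, if its minor
    allele frequency is at or below ``min_maf_exclusive`` (so MAF == 0.02 is
    excluded at the default threshold), or if its Hardy-Weinberg chi-square
    exceeds ``max_hwe_chisq``.  Allele frequencies are recomputed on the
    call-rate survivors before the MAF and HWE filters.  Returns the filtered
    matrix and a report with the count removed by each filter.
    """
    thresholds = thresholds or QCThresholds()
    keep = np.ones(genotypes.n_snps, dtype=bool)

    cr = genotypes.call_rate()
    fail_cr = cr < thresholds.min_call_rate
    keep &= ~fail_cr

    sub = GenotypeMatrix(genotypes.ids, genotypes.snp_ids[keep], genotypes.X[:, keep])
    p = sub.allele_freq()
    maf = np.minimum(p, 1 - p)
    fail_maf_local = maf <= thresholds.min_maf_exclusive
    fail_maf = np.zeros_like(keep)
    fail_maf[np.flatnonzero(keep)[fail_maf_local]] = True
    keep &= ~fail_maf

    sub = GenotypeMatrix(genotypes.ids, genotypes.snp_ids[keep], genotypes.X[:, keep])
    chis = _hwe_chisq(sub.X)
    fail_hwe_local = chis > thresholds.max_hwe_chisq
    fail_hwe = np.zeros_like(keep)
    fail_hwe[np.flatnonzero(keep)[fail_hwe_local]] = True
    keep &= ~fail_hwe

    report = pd.DataFrame(
        {
            "filter": ["call_rate", "maf", "hwe"],
            "n_removed": [int(fail_cr.sum()), int(fail_maf.sum()), int(fail_hwe.sum())],
        }
    )
    report.loc[len(report)] = ["retained", int(keep.sum())]
    if keep.sum() == 0:
        raise AllSNPsRemoved("quality control removed every SNP")
    out = GenotypeMatrix(genotypes.ids, genotypes.snp_ids[keep], genotypes.X[:, keep])
    return out, report


def build_A(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    Founders get diagonal 1 and zero relationship with other founders;
    a_ij = (a_i,sire(j) + a_i,dam(j)) / 2 for i < j and
    a_jj = 1 + a_sire(j),dam(j) / 2 (inbreeding handled exactly).
    """
    n = pedigree.n
    sire, dam = pedigree.parent_arrays()
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        if s >= j or d >= j:
            raise ValueError("pedigree must be sorted parents-first (acyclic)")
        A[j, j] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
        contrib = np.zeros(j)
        if s >= 0:
            contrib += 0.5 * A[:j, s]
        if d >= 0:
            contrib += 0.5 * A[:j, d]
        A[:j, j] = contrib
        A[j, :j] = contrib
    return A


def A_inverse(pedigree: Pedigree, A: np.ndarray | None = None) -> np.ndarray:
    """Inverse of A by Henderson's rules with inbreeding.

    Uses the Mendelian-sampling variances d_j = a_jj - (a_ss + a_dd)/4 taken
    from the tabular A (Quaas' adjustment), so the result is exact for inbred
    pedigrees as well.
    """
    if A is None:
        A = build_A(pedigree)
    n = pedigree.n
    sire, dam = pedigree.parent_arrays()
    Ainv = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        # Mendelian-sampling variance: 1 - (a_ss + a_dd)/4 over known parents
        # (equivalently 1/2 - (F_s + F_d)/4 with both parents known)
        dj = 1.0
        if s >= 0:
            dj -= 0.25 * A[s, s]
        if d >= 0:
            dj -= 0.25 * A[d, d]
        w = 1.0 / dj
        Ainv[j, j] += w
        for p in (s, d):
            if p >= 0:
                Ainv[j, p] -= 0.5 * w
                Ainv[p, j] -= 0.5 * w
                Ainv[p, p] += 0.25 * w
        if s >= 0 and d >= 0:
            Ainv[s, d] += 0.25 * w
            Ainv[d, s] += 0.25 * w
    return Ainv


def subset_A(A: np.ndarray, pedigree: Pedigree, ids: np.ndarray) -> np.ndarray:
    """A22: the block of A for the given (genotyped) animal IDs, in order."""
    ix = np.asarray(ids) - 1
    return A[np.ix_(ix, ix)]


def build_G(genotypes: GenotypeMatrix) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix, observed frequencies.

        G = (M - 2P)(M - 2P)' / (2 * sum_j p_j (1 - p_j))

    Missing genotypes are imputed to twice the observed allele frequency
    (the column mean) before centering.
    """
    p = genotypes.allele_freq()
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic; G denominator is zero")
    M = genotypes.X.astype(float)
    miss = genotypes.X == GenotypeMatrix.MISSING
    if miss.any():
        M[miss] = np.broadcast_to(2.0 * p, M.shape)[miss]
    Z = M - 2.0 * p
    return Z @ Z.T / denom


def blend_H_inverse(
    A_inv: np.ndarray,
    A22: np.ndarray,
    G: np.ndarray,
    genotyped_index: np.ndarray,
    alpha: float = 0.95,
    beta_convention: str = "as_printed",
) -> np.ndarray:
    """Single-step blended inverse relationship matrix.

    ``genotyped_index`` gives the 0-based positions, within the full pedigree
    ordering of ``A_inv``, of the animals whose rows/columns of ``A22`` and
    ``G`` are supplied (identical order required).  ``beta_convention``
    selects beta = 2 - alpha (``"as_printed"``, the default used throughout
    this package) or beta = 1 - alpha (``"complement"``).
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if A22.shape != G.shape or A22.shape[0] != len(genotyped_index):
        raise ValueError("A22 and G must be conformable with genotyped_index")
    beta = (2.0 - alpha) if beta_convention == "as_printed" else (1.0 - alpha)
    Gw = alpha * G + beta * A22
    # reject an ill-conditioned blend with actionable guidance
    try:
        c = np.linalg.cholesky(Gw)
        Gw_inv = np.linalg.inv(c.T) @ np.linalg.inv(c)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "alpha*G + beta*A22 is singular; lower alpha to regress G further towards A22"
        ) from err
    A22_inv = np.linalg.inv(A22)
    H_inv = A_inv.copy()
    ix = np.ix_(genotyped_index, genotyped_index)
    H_inv[ix] += Gw_inv - A22_inv
    return H_inv


def var_offdiag(M: np.ndarray) -> float:
    """Unbiased variance of the strictly-upper-triangle entries."""
    if not np.allclose(M, M.T):
        raise ValueError("matrix must be symmetric")
    iu = np.triu_indices(M.shape[0], k=1)
    vals = M[iu]
    if vals.size < 2:
        raise ValueError("need at least two off-diagonal pairs")
    return float(np.var(vals, ddof=1))


@dataclass
class GenomicArchitecture:
    """LD summaries among genotyped animals: Me and relationship variances."""

    Me: float
    var_offdiag_A: float
    var_G_minus_A22: float


def compute_Me(G: np.ndarray, A22: np.ndarray) -> GenomicArchitecture:
    """Effective number of segregating segments, Me = 1 / var(G - A22).

    The variance is taken over off-diagonal pairs of genotyped animals only.
    A zero variance (G identical to A22, i.e. no linkage disequilibrium
    signal) yields an infinite Me.
    """
    if G.shape != A22.shape:
        raise ValueError("G and A22 must be conformable")
    v = var_offdiag(G - A22)
    me = np.inf if v == 0 else 1.0 / v
    return GenomicArchitecture(
        Me=float(me),
        var_offdiag_A=var_offdiag(A22),
        var_G_minus_A22=float(v),
    )
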