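"""Pool-level genomic relationship matrix (VanRaden method 1 for F2 pools).

The frequency matrix X (SNPs x families) is centered by per-SNP mean
frequencies, missing cells are mean-imputed (exactly 0 after centering), and

    G = M'M / K,      K = 0.25 * sum_i  Xbar_i (1 - Xbar_i),

where K is the sum of expected per-SNP variances of F2 pool frequencies in
the absence of inbreeding.  Centering makes G singular (row sums zero), so
the inverse is computed from the eigendecomposition after repairing the
smallest eigenvalue to just below the second smallest.

An optional missing-rate correction rescales each element by a pairwise
constant K_jk accumulated only over SNPs observed in both families, so that
relationships between poorly genotyped samples are not shrunk by
zero-imputed cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .errors import DegenerateDataError, ValidationError
from .snp_filters import PoolFrequencyMatrix


@dataclass
class CenteredMatrix:
    """Centered frequency matrix M (SNPs x families) and the SNP means."""

    M: np.ndarray
    snp_means: np.ndarray
    missing: np.ndarray
    family_ids: list


@dataclass
class GenomicRelationshipMatrix:
    G: np.ndarray                     # family x family, symmetric
    K: float                          # scaling constant
    mean_diagonal: float
    family_ids: list
    pair_scaling: Optional[np.ndarray] = None  # K_jk when missing-corrected

    @property
    def n_families(self) -> int:
        return self.G.shape[0]

    @property
    def mean_offdiagonal(self) -> float:
        n = self.n_families
        return float((self.G.sum() - np.trace(self.G)) / (n * (n - 1)))


@dataclass
class RepairedInverse:
    G_inv: np.ndarray
    eigenvalues_before: np.ndarray    # ascending
    eigenvalues_after: np.ndarray
    repair_factor: float


def _as_pool_matrix(matrix) -> PoolFrequencyMatrix:
    if isinstance(matrix, PoolFrequencyMatrix):
        return matrix
    return PoolFrequencyMatrix(values=np.asarray(matrix, dtype=float))


def center_and_impute(matrix: Union[PoolFrequencyMatrix, np.ndarray]) -> CenteredMatrix:
    """M_ij = X_ij - Xbar_i for observed cells, 0 (mean imputation) if missing.

    Xbar_i is computed over non-missing cells only; a SNP with no observed
    cell raises an error naming it.
    """
    pm = _as_pool_matrix(matrix)
    means = pm.mean_frequencies()
    M = np.where(pm.missing, 0.0, pm.values - means[:, None])
    return CenteredMatrix(M=M, snp_means=means, missing=pm.missing, family_ids=pm.family_ids)


def scaling_constant(snp_means: np.ndarray) -> float:
    """K = 0.25 * sum Xbar_i (1 - Xbar_i); errors when zero (GRM undefined)."""
    m = np.asarray(snp_means, dtype=float)
    if m.size and (m.min() < 0 or m.max() > 1):
        raise ValidationError("SNP mean frequencies must lie in [0, 1]")
    K = 0.25 * float(np.sum(m * (1.0 - m)))
    if K == 0.0:
        raise DegenerateDataError("scaling constant K is zero; GRM undefined")
    return K


def compute_grm(
    matrix: Union[PoolFrequencyMatrix, np.ndarray],
    missing_correction: bool = False,
) -> GenomicRelationshipMatrix:
    """G = M'M / K, optionally with the pairwise missing-rate correction.

    With the correction, element (j, k) is divided by
    K_jk = 0.25 * sum over SNPs observed in both j and k of Xbar_i(1-Xbar_i)
    instead of the global K.
    """
    pm = _as_pool_matrix(matrix)
    cm = center_and_impute(pm)
    K = scaling_constant(cm.snp_means)
    MtM = cm.M.T @ cm.M
    pair_scaling = None
    if missing_correction:
        w = 0.25 * cm.snp_means * (1.0 - cm.snp_means)
        obs = (~cm.missing).astype(float)
        pair_scaling = obs.T @ (w[:, None] * obs)
        zero = pair_scaling == 0
        if zero.any():
            j, k = np.argwhere(zero)[0]
            raise DegenerateDataError(
                f"pairwise scaling constant is zero for families "
                f"({pm.family_ids[j]}, {pm.family_ids[k]})"
            )
        G = MtM / pair_scaling
    else:
        G = MtM / K
    G = 0.5 * (G + G.T)  # enforce exact symmetry
    return GenomicRelationshipMatrix(
        G=G,
        K=K,
        mean_diagonal=float(np.mean(np.diag(G))),
        family_ids=pm.family_ids,
        pair_scaling=pair_scaling,
    )


def invert_grm(
    G: Union[GenomicRelationshipMatrix, np.ndarray],
    repair_factor: float = 0.99,
) -> RepairedInverse:
    """Invert G after repairing its (near-)zero smallest eigenvalue.

    The smallest eigenvalue is replaced by ``repair_factor`` times the second
    smallest ("a value just below the one-by-last eigenvalue"); the inverse is
    assembled from the repaired spectrum as E diag(1/lambda) E'.
    """
    A = G.G if isinstance(G, GenomicRelationshipMatrix) else np.asarray(G, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("G must be square")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValidationError("G must be symmetric")
    if not 0 < repair_factor < 1:
        raise ValidationError("repair_factor must lie in (0, 1)")
    vals, vecs = np.linalg.eigh(A)  # ascending
    if vals.size < 2 or vals[1] <= 0:
        raise DegenerateDataError(
            "second-smallest eigenvalue is not positive; matrix not repairable"
        )
    repaired = vals.copy()
    repaired[0] = repair_factor * vals[1]
    G_inv = (vecs / repaired) @ vecs.T
    G_inv = 0.5 * (G_inv + G_inv.T)
    return RepairedInverse(
        G_inv=G_inv,
        eigenvalues_before=vals,
        eigenvalues_after=repaired,
        repair_factor=repair_factor,
    )
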