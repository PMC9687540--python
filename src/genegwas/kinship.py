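"""Realized relationship matrix (RRM) and its one-time spectral decomposition.

The RRM is computed from all post-filter markers and decomposed once,
K = U diag(S) U^T; every gene test then reuses (U, S) to whiten the mixed
model into a weighted regression (the FaST-LMM device).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import GeneGwasError
from .panel import GenotypePanel

logger = logging.getLogger(__name__)

#: Relative tolerance for symmetry checks and eigenvalue clipping.
EIG_TOL = 1e-8


@dataclass
class SpectralKinship:
    """Kinship matrix with its eigendecomposition (eigenvalues descending)."""

    K: np.ndarray
    U: np.ndarray
    S: np.ndarray

    @property
    def n(self) -> int:
        return self.K.shape[0]


def compute_rrm(panel: GenotypePanel, method: str = "vanraden") -> np.ndarray:
    """Realized relationship matrix from all panel markers.

    ``vanraden``
        K = Xc Xc^T / (2 * sum_j p_j (1 - p_j)) with Xc the column-centered
        (mean-imputed) dosage matrix and p_j the alternate-allele frequency.
    ``correlation``
        the standardized-SNP average: each centered column divided by
        sqrt(2 p_j (1 - p_j)), K = Xs Xs^T / m.
    """
    if panel.n_snps == 0:
        raise GeneGwasError("cannot compute kinship from an empty panel")
    X = panel.imputed()
    p = panel.allele_freq
    Xc = X - X.mean(axis=0)
    het = 2.0 * p * (1.0 - p)
    if method == "vanraden":
        denom = het.sum()
        if denom <= 0:
            raise GeneGwasError("all SNPs monomorphic: RRM denominator is zero")
        K = (Xc @ Xc.T) / denom
    elif method == "correlation":
        ok = het > 0
        if not ok.any():
            raise GeneGwasError("all SNPs monomorphic: RRM denominator is zero")
        Xs = Xc[:, ok] / np.sqrt(het[ok])
        K = (Xs @ Xs.T) / ok.sum()
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    return 0.5 * (K + K.T)  # symmetrize against rounding


def spectral_decompose(K: np.ndarray) -> SpectralKinship:
    """Eigendecompose a symmetric PSD kinship matrix.

    Eigenpairs are returned in descending eigenvalue order. Tiny negative
    eigenvalues (numerical noise) are clipped to zero; genuinely negative
    ones raise an error.
    """
    K = np.asarray(K, dtype=np.float64)
    scale = max(1.0, float(np.abs(K).max()))
    if np.abs(K - K.T).max() > EIG_TOL * scale:
        raise GeneGwasError("kinship matrix is not symmetric")
    S, U = np.linalg.eigh(K)
    S = S[::-1].copy()
    U = U[:, ::-1].copy()
    tol = EIG_TOL * max(1.0, float(S[0]) if S.size else 1.0)
    if S[-1] < -tol:
        raise GeneGwasError(
            f"kinship matrix has negative eigenvalue {S[-1]:.3e}"
        )
    np.clip(S, 0.0, None, out=S)
    return SpectralKinship(K=K, U=U, S=S)


def identity_spectral(n: int) -> SpectralKinship:
    """Spectral object for K = I (used by the plain-linear-model mode)."""
    return SpectralKinship(K=np.eye(n), U=np.eye(n), S=np.ones(n))
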