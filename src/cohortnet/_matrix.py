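"""Correlation-matrix utilities: validity checks and nearest-PSD repair."""

from __future__ import annotations

import numpy as np

__all__ = ["is_valid_correlation", "nearest_psd_correlation", "PSDRepairError"]


class PSDRepairError(ValueError):
    """Raised when a matrix cannot be repaired into a valid correlation matrix."""


def is_valid_correlation(mat: np.ndarray, tol: float = 1e-8) -> bool:
    """True if `mat` is symmetric, unit-diagonal, entries in [-1, 1] and PSD."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        return False
    if not np.allclose(mat, mat.T, atol=tol):
        return False
    if not np.allclose(np.diag(mat), 1.0, atol=tol):
        return False
    if np.any(np.abs(mat) > 1.0 + tol):
        return False
    eigvals = np.linalg.eigvalsh((mat + mat.T) / 2.0)
    return bool(eigvals.min() >= -tol)


def nearest_psd_correlation(
    mat: np.ndarray,
    eig_floor: float = 1e-8,
    max_iter: int = 50,
) -> np.ndarray:
    """Project a symmetric matrix onto the correlation matrices.

    Eigenvalue clipping at `eig_floor` followed by re-standardising the
    diagonal to 1, iterated until both constraints hold.  Suitable for
    matrices that are already close to valid (small indefiniteness from
    planting effects); not a general-purpose alternating-projections solver.
    """
    out = (np.asarray(mat, dtype=float) + np.asarray(mat, dtype=float).T) / 2.0
    np.clip(out, -1.0, 1.0, out=out)
    np.fill_diagonal(out, 1.0)
    for _ in range(max_iter):
        eigvals, eigvecs = np.linalg.eigh(out)
        if eigvals.min() >= eig_floor / 2:
            break
        eigvals = np.clip(eigvals, eig_floor, None)
        out = (eigvecs * eigvals) @ eigvecs.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = (out + out.T) / 2.0
        np.clip(out, -1.0, 1.0, out=out)
        np.fill_diagonal(out, 1.0)
    else:
        raise PSDRepairError("PSD repair did not converge")
    return out
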