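"""Two-dimensional PCA of paired dual-energy measurements.

The measurement matrix ``X`` holds one row per voxel, columns = (low-,
high-energy HU).  The model is the mean vector, the orthonormal
eigenvector matrix ``W`` (columns = principal axes) and the descending
eigenvalues of the sample covariance ``C = X~^T X~ / (N - 1)``.  Because
``W`` is a rotation (or reflection), the projection preserves Euclidean
distances, triangle areas up to sign, and hence barycentric coordinates;
the decomposition geometry is carried out in this rotated space.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = ["PCAModel", "fit_pca", "pca_transform", "pca_inverse_transform"]


@dataclasses.dataclass(frozen=True)
class PCAModel:
    """Fitted PCA: mean (2,), eigenvectors W (2, 2; columns), eigenvalues (2,)."""

    mean: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self):
        W = np.asarray(self.eigenvectors, dtype=float)
        lam = np.asarray(self.eigenvalues, dtype=float)
        mean = np.asarray(self.mean, dtype=float)
        if mean.shape != (2,) or W.shape != (2, 2) or lam.shape != (2,):
            raise ValueError("PCAModel expects 2-D mean/eigenvalues and 2x2 eigenvectors")
        if not np.allclose(W.T @ W, np.eye(2), atol=1e-10):
            raise ValueError("eigenvectors must be orthonormal")
        if lam[0] < lam[1] - 1e-12 or np.any(lam < -1e-12):
            raise ValueError("eigenvalues must be sorted descending and non-negative")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "eigenvectors", W)
        object.__setattr__(self, "eigenvalues", np.maximum(lam, 0.0))


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (deterministic)."""
    W = W.copy()
    for j in range(W.shape[1]):
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return W


def fit_pca(points: np.ndarray) -> PCAModel:
    """Fit the 2-D PCA model on an (N, 2) stack of measurements.

    The mean is taken over all rows; the covariance uses the unbiased
    1/(N-1) normalization.  If the covariance vanishes (all rows
    identical), the eigenvectors fall back to the identity with a
    warning -- the decomposition is rotation-invariant, so this only
    affects the serialized model, not the result.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("expected an (N, 2) array of dual-energy measurements")
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 measurements")
    if not np.all(np.isfinite(X)):
        raise ValueError("measurements must be finite")

    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    if np.allclose(cov, 0.0, atol=1e-30):
        warnings.warn(
            "zero covariance (all measurements identical); using identity axes",
            RuntimeWarning,
            stacklevel=2,
        )
        return PCAModel(mean=mean, eigenvectors=np.eye(2), eigenvalues=np.zeros(2))

    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    # stable descending sort: equal eigenvalues keep eigh's order, so an
    # isotropic cloud yields the identity under the sign convention
    order = np.argsort(-eigenvalues, kind="stable")
    eigenvalues = np.maximum(eigenvalues[order], 0.0)
    eigenvectors = _fix_signs(eigenvectors[:, order])
    return PCAModel(mean=mean, eigenvectors=eigenvectors, eigenvalues=eigenvalues)


def pca_transform(model: PCAModel, points: np.ndarray) -> np.ndarray:
    """Project points into PCA space: ``W^T (x - mean)``."""
    p = np.asarray(points, dtype=float)
    return (p - model.mean) @ model.eigenvectors


def pca_inverse_transform(model: PCAModel, points: np.ndarray) -> np.ndarray:
    """Map PCA-space points back to the original attenuation space."""
    p = np.asarray(points, dtype=float)
    return p @ model.eigenvectors.T + model.mean
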