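"""Whitening of sensor mixtures prior to source separation.

IVA, like ICA, is fitted on whitened data: each dataset is mapped by an
invertible linear transform so that its sample covariance becomes the
identity.  The transform is computed once on training data and then frozen,
so validation/test trials are projected with the training statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError

__all__ = ["WhiteningTransform", "fit_whitening", "apply_whitening"]


@dataclass(frozen=True)
class WhiteningTransform:
    """Linear map ``z = V (x - mean)`` with unit output covariance on the fit data.

    Attributes
    ----------
    V : ndarray of shape (M, M)
        Whitening matrix, ``V = Lambda^{-1/2} E^T`` from the eigendecomposition
        of the sample covariance ``C = E Lambda E^T``.
    mean : ndarray of shape (M,)
        Channel means of the fitting data.
    """

    V: np.ndarray
    mean: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.V.shape[0]


def fit_whitening(X: np.ndarray, rank_tol: float = 1e-10) -> WhiteningTransform:
    """Fit a whitening transform to an ``(M, N)`` data matrix.

    All M dimensions are retained; a rank-deficient covariance is an error
    (reduce the channel set instead of silently dropping dimensions by PCA).

    Parameters
    ----------
    X : ndarray of shape (M, N)
        One dataset, channels by samples, with ``N > M``.
    rank_tol : float
        Relative eigenvalue threshold below which the covariance is
        considered rank deficient.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise DataError(f"expected a 2-D (channels, samples) matrix, got shape {X.shape}")
    M, N = X.shape
    if N <= M:
        raise DataError(f"need more samples than channels to whiten (M={M}, N={N})")
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    C = (Xc @ Xc.T) / N
    evals, evecs = np.linalg.eigh(C)
    if evals[0] <= rank_tol * evals[-1]:
        raise DataError(
            "sample covariance is rank deficient "
            f"(min/max eigenvalue ratio {evals[0] / evals[-1]:.2e}); "
            "remove redundant channels (e.g. use a channel subset) before whitening"
        )
    V = (evecs / np.sqrt(evals)).T  # Lambda^{-1/2} E^T
    return WhiteningTransform(V=V, mean=mean)


def apply_whitening(transform: WhiteningTransform, X: np.ndarray) -> np.ndarray:
    """Apply ``z = V (x - mean)`` to an ``(M, N)`` matrix (or ``(n, M, T)`` trials)."""
    X = np.asarray(X, dtype=np.float64)
    M = transform.n_channels
    if X.ndim == 2:
        if X.shape[0] != M:
            raise DataError(f"data have {X.shape[0]} rows, transform expects {M}")
        return transform.V @ (X - transform.mean[:, None])
    if X.ndim == 3:
        if X.shape[1] != M:
            raise DataError(f"trials have {X.shape[1]} channels, transform expects {M}")
        return np.einsum("ij,njt->nit", transform.V, X - transform.mean[None, :, None])
    raise DataError(f"expected 2-D or 3-D input, got shape {X.shape}")
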