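"""Yule-Walker AR(q) coefficients as classifier features.

Each extracted component time series is summarised by the coefficients of an
autoregressive model ``u(n) = a1 u(n-1) + ... + aq u(n-q) + v(n)``, estimated
from the Yule-Walker normal equations ``a = R_u^{-1} r_u`` built from biased
(1/T) sample autocovariances of the mean-removed signal.  AR coefficients are
invariant to scaling and sign-flipping of the signal, which neutralises the
scale/sign ambiguity inherent to blind source separation outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, solve_toeplitz

from .exceptions import DataError

__all__ = ["ARFeatures", "yule_walker", "extract_ar_features"]


@dataclass
class ARFeatures:
    """AR coefficients per trial and channel.

    ``coeffs`` has shape (n_trials, n_channels, q).  ``noise_var`` (the
    innovation variance) is retained for diagnostics but is not part of the
    feature vector.
    """

    coeffs: np.ndarray
    q: int
    noise_var: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        """Feature matrix (n_trials, n_channels * q), channel-major."""
        n = self.coeffs.shape[0]
        return self.coeffs.reshape(n, -1)


def _autocovariance(u: np.ndarray, q: int) -> np.ndarray:
    """Biased sample autocovariances r(0..q) of the mean-removed signal."""
    T = u.shape[0]
    uc = u - u.mean()
    full = np.correlate(uc, uc, mode="full")
    return full[T - 1 : T + q] / T


def yule_walker(u: np.ndarray, q: int) -> tuple[np.ndarray, float]:
    """Estimate AR(q) coefficients and innovation variance of one signal.

    Solves the Toeplitz system ``R_u a = r_u`` where ``R_u[i, j] = r(|i-j|)``
    and ``r_u = (r(1), ..., r(q))``; the innovation variance is
    ``r(0) - a . r_u``.

    Raises for a constant signal (zero variance) or a singular ``R_u``.
    """
    u = np.asarray(u, dtype=np.float64).ravel()
    T = u.shape[0]
    if q < 1:
        raise DataError(f"AR order must be >= 1, got {q}")
    if T <= q + 1:
        raise DataError(f"signal length {T} too short for AR({q}); need T > q + 1")
    r = _autocovariance(u, q)
    # a nominally constant signal leaves only rounding residue after demeaning
    if r[0] <= 0 or r[0] < 1e-20 * np.mean(u * u):
        raise DataError("constant (zero-variance) signal has no AR representation")
    try:
        a = solve_toeplitz(r[:q], r[1 : q + 1])
    except LinAlgError as exc:
        raise DataError("singular autocovariance matrix in Yule-Walker system") from exc
    if not np.all(np.isfinite(a)):
        raise DataError("singular autocovariance matrix in Yule-Walker system")
    noise_var = float(r[0] - a @ r[1 : q + 1])
    return a, noise_var


def extract_ar_features(trials: np.ndarray, q: int = 4) -> ARFeatures:
    """Fit :func:`yule_walker` independently per trial and channel.

    ``trials`` has shape (n_trials, n_channels, T).  The per-trial feature
    vector is the flattened (n_channels, q) coefficient block, channel-major.
    """
    trials = np.asarray(trials, dtype=np.float64)
    if trials.ndim != 3:
        raise DataError(f"trials must be (n_trials, channels, T); got shape {trials.shape}")
    n, C, T = trials.shape
    if q < 1:
        raise DataError(f"AR order must be >= 1, got {q}")
    if T <= q + 1:
        raise DataError(f"trial length {T} too short for AR({q}); need T > q + 1")

    # batched autocovariances r(0..q): r_j = mean_t u(t) u(t+j), mean-removed
    uc = trials - trials.mean(axis=2, keepdims=True)
    r = np.empty((n, C, q + 1))
    for j in range(q + 1):
        r[:, :, j] = np.einsum("nct,nct->nc", uc[:, :, : T - j], uc[:, :, j:]) / T
    power = np.mean(trials * trials, axis=2)
    bad = np.argwhere((r[:, :, 0] <= 0) | (r[:, :, 0] < 1e-20 * power))
    if bad.size:
        i, c = bad[0]
        raise DataError(f"trial {i}, channel {c}: constant (zero-variance) signal has no AR representation")

    idx = np.abs(np.arange(q)[:, None] - np.arange(q)[None, :])
    R = r[:, :, idx]  # (n, C, q, q) Toeplitz blocks
    try:
        coeffs = np.linalg.solve(R, r[:, :, 1:, None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise DataError("singular autocovariance matrix in Yule-Walker system") from exc
    if not np.all(np.isfinite(coeffs)):
        i, c = np.argwhere(~np.isfinite(coeffs).all(axis=2))[0]
        raise DataError(f"trial {i}, channel {c}: singular Yule-Walker system")
    noise_var = r[:, :, 0] - np.einsum("ncq,ncq->nc", coeffs, r[:, :, 1:])
    return ARFeatures(coeffs=coeffs, q=q, noise_var=noise_var)
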