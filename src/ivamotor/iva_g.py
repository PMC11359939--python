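"""IVA-G: independent vector analysis with multivariate Gaussian sources.

Joint blind source separation of K datasets.  The m-th source component
vector (SCV) collects component m across the K datasets,
``y_m = [y_m^[1], ..., y_m^[K]]``; SCVs are mutually independent while the
entries within an SCV are correlated.  Under the Gaussian SCV model only
second-order statistics enter, and the (constant-free) cost is

    J(W) = sum_m 1/2 log det Sigma_m  -  sum_k log |det W^[k]|,

with ``Sigma_m`` the sample covariance of SCV m under the current demixing
matrices.  Minimisation is by vector gradient descent: each demixing row
``w_m^[k]`` is updated in turn, using the decoupling vector ``h_m^[k]``
(unit vector orthogonal to the other rows of ``W^[k]``) to express the
row-wise derivative of ``log |det W^[k]|``, followed by renormalisation of
the row to unit length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConvergenceError, DataError

__all__ = [
    "DemixingSet",
    "SCVStatistics",
    "scv_covariances",
    "gaussian_score",
    "decoupling_vector",
    "iva_cost",
    "iva_gradient_row",
    "fit_iva_g",
    "joint_isi",
]

logger = logging.getLogger(__name__)

# step-size shrink factor applied when a sweep fails to decrease the cost
_ANNEAL = 0.9
# below this step size no further progress is possible in double precision
_MU_MIN = 1e-8


@dataclass
class DemixingSet:
    """K square demixing matrices plus fit diagnostics.

    ``W[k]`` maps the whitened dataset k to component estimates; rows are
    kept at unit norm after every accepted update.
    """

    W: list[np.ndarray]
    converged: bool = False
    n_iter: int = 0
    cost_trajectory: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_datasets(self) -> int:
        return len(self.W)

    @property
    def n_components(self) -> int:
        return self.W[0].shape[0]


@dataclass
class SCVStatistics:
    """Sample covariance of each source component vector.

    ``Sigma[m]`` is the K-by-K covariance of component m across datasets.
    """

    Sigma: list[np.ndarray]


def _as_stack(Y) -> np.ndarray:
    """Coerce a list of K (M, N) matrices (or a (K, M, N) array) to a 3-D array."""
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim != 3:
        raise DataError(f"expected K matrices of shape (M, N), got array shape {Y.shape}")
    return Y


def scv_covariances(Y) -> SCVStatistics:
    """Sample covariances of all M SCVs from K component matrices.

    Uses the biased (1/N) estimator after mean removal.  A ridge
    ``eps * I`` with ``eps = 1e-10 * trace / K`` is added to any Sigma_m
    whose smallest eigenvalue falls below eps, keeping the matrices safely
    positive definite.
    """
    Y = _as_stack(Y)
    K, M, N = Y.shape
    if N <= K:
        raise DataError(f"need more samples than datasets to estimate SCV covariances (K={K}, N={N})")
    Yc = Y - Y.mean(axis=2, keepdims=True)
    # Sigma[m] = Yc[:, m, :] @ Yc[:, m, :].T / N for every m at once
    Sig = np.einsum("kmn,lmn->mkl", Yc, Yc) / N
    out = []
    for m in range(M):
        S = Sig[m]
        eps = 1e-10 * np.trace(S) / K
        if np.linalg.eigvalsh(S)[0] < eps:
            S = S + eps * np.eye(K)
        out.append(S)
    return SCVStatistics(Sigma=out)


def gaussian_score(y_m: np.ndarray, Sigma_m: np.ndarray) -> np.ndarray:
    """Gaussian score of one SCV sample: ``Sigma_m^{-1} y_m``.

    Element k is minus the derivative of the SCV log-density with respect to
    ``y_m^[k]`` under the zero-mean Gaussian model.
    """
    y_m = np.asarray(y_m, dtype=np.float64)
    Sigma_m = np.asarray(Sigma_m, dtype=np.float64)
    try:
        return np.linalg.solve(Sigma_m, y_m)
    except np.linalg.LinAlgError as exc:
        raise DataError("singular SCV covariance") from exc


def decoupling_vector(W, m: int, k: int) -> np.ndarray:
    """Unit vector orthogonal to all rows of ``W^[k]`` except row m.

    The sign is fixed so that ``h . w_m^[k] > 0``.  Raises if the remaining
    rows are rank deficient (the null space would not be one-dimensional).
    """
    Wk = W.W[k] if isinstance(W, DemixingSet) else np.asarray(W[k], dtype=np.float64)
    M = Wk.shape[0]
    if M == 1:
        return np.ones(1)
    W_tilde = np.delete(Wk, m, axis=0)
    # null space of the (M-1, M) matrix via SVD
    _, s, Vt = np.linalg.svd(W_tilde)
    if s[-1] <= 1e-12 * s[0]:
        raise DataError(f"rows of W^[{k}] other than {m} are rank deficient; no unique decoupling vector")
    h = Vt[-1]
    d = h @ Wk[m]
    if d < 0:
        h = -h
    return h


def _cost_from_components(Y: np.ndarray, W: list[np.ndarray]) -> float:
    """Cost given precomputed components Y[k] = W[k] @ Z[k]."""
    K = Y.shape[0]
    stats = scv_covariances(Y)
    cost = 0.0
    for S in stats.Sigma:
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            return np.inf
        cost += 0.5 * logdet
    for k in range(K):
        sign, logdet = np.linalg.slogdet(W[k])
        if sign == 0:
            warnings.warn("non-invertible demixing matrix; cost is +inf", stacklevel=3)
            return np.inf
        cost += -logdet
    return float(cost)


def iva_cost(W, Z) -> float:
    """IVA-G cost ``sum_m 1/2 log det Sigma_m - sum_k log |det W^[k]|``.

    Entropy constants and the ``(2*pi*e)`` terms are dropped: they shift the
    value but not the minimiser.  Returns ``+inf`` (with a warning) for a
    non-invertible demixing matrix.
    """
    Wmats = W.W if isinstance(W, DemixingSet) else [np.asarray(Wk, dtype=np.float64) for Wk in W]
    Z = _as_stack(Z)
    Y = np.einsum("kij,kjn->kin", np.stack(Wmats), Z)
    return _cost_from_components(Y, Wmats)


def iva_gradient_row(W, Z, Sigma: SCVStatistics, m: int, k: int) -> np.ndarray:
    """Gradient of the IVA-G cost with respect to demixing row ``w_m^[k]``.

    Equals ``E{phi^[k](y_m) z^[k]} - h_m^[k] / (h_m^[k] . w_m^[k])`` where
    ``phi^[k](y_m) = [Sigma_m^{-1} y_m]_k`` is the Gaussian score.  With
    Sigma_m taken as the sample covariance of the current components, the
    expectation term is the exact derivative of ``1/2 log det Sigma_m``, so
    the whole expression matches finite differences of :func:`iva_cost`.
    """
    Wmats = W.W if isinstance(W, DemixingSet) else [np.asarray(Wk, dtype=np.float64) for Wk in W]
    Z = _as_stack(Z)
    K, M, N = Z.shape
    # component m across datasets under the current rows
    Y_m = np.stack([Wmats[j][m] @ Z[j] for j in range(K)])
    Y_m = Y_m - Y_m.mean(axis=1, keepdims=True)
    S = np.linalg.solve(Sigma.Sigma[m], Y_m)  # scores, (K, N)
    Zc = Z[k] - Z[k].mean(axis=1, keepdims=True)
    term1 = Zc @ S[k] / N
    h = decoupling_vector(Wmats, m, k)
    d = h @ Wmats[k][m]
    if d == 0.0:
        raise DataError(f"degenerate demixing matrix: decoupling vector orthogonal to row {m} of W^[{k}]")
    grad = term1 - h / d
    if not np.all(np.isfinite(grad)):
        raise DataError(f"non-finite gradient for row {m} of W^[{k}]")
    return grad


def _normalize_rows(Wk: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Wk, axis=1, keepdims=True)
    if not np.all(np.isfinite(norms)) or np.any(norms == 0):
        raise DataError("demixing matrix has a zero or non-finite row; cannot normalise")
    return Wk / norms


def fit_iva_g(
    Z,
    W_init: np.ndarray | list[np.ndarray],
    mu: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 512,
) -> DemixingSet:
    """Fit IVA-G by decoupled vector gradient descent.

    Each iteration sweeps every row ``(m, k)``: a gradient step of size
    ``mu`` followed by renormalisation of the row to unit length.  SCV
    covariances are re-estimated once per full sweep.  A sweep that fails to
    decrease the cost is rejected: the matrices are restored and the step
    size is shrunk by 0.9 before retrying (a fixed step of 1 provably
    limit-cycles around the minimum on typical whitened instances), so the
    accepted cost sequence is non-increasing.  Iteration stops when the
    absolute cost change of an accepted sweep falls below ``tol``, when the
    step size underflows, or after ``max_iter`` sweep attempts.

    Parameters
    ----------
    Z : K matrices of shape (M, N)
        Whitened datasets.
    W_init : ndarray (M, M) or list of K such
        A single matrix is replicated to all K datasets (the same random
        initialisation shared across subjects).
    mu : float
        Initial step size.
    """
    Z = _as_stack(Z)
    K, M, N = Z.shape
    W_init = np.asarray(W_init, dtype=np.float64)
    if W_init.ndim == 2:
        W = [_normalize_rows(W_init.copy()) for _ in range(K)]
    elif W_init.ndim == 3 and W_init.shape[0] == K:
        W = [_normalize_rows(W_init[k].copy()) for k in range(K)]
    else:
        raise DataError(f"W_init must be (M, M) or (K, M, M); got {W_init.shape}")
    if W[0].shape != (M, M):
        raise DataError(f"W_init shape {W[0].shape} does not match data dimension M={M}")

    Zc = Z - Z.mean(axis=2, keepdims=True)
    Y = np.einsum("kij,kjn->kin", np.stack(W), Z)

    cost = _cost_from_components(Y, W)
    trajectory = [cost]
    converged = False
    it = 0

    for it in range(1, max_iter + 1):
        W_prev = [Wk.copy() for Wk in W]
        Y_prev = Y.copy()
        Sigma = scv_covariances(Y)
        for m in range(M):
            # current component m, centred, and its scores under fixed Sigma;
            # scores are rank-1-updated as rows change within the block
            Y_m = Y[:, m, :] - Y[:, m, :].mean(axis=1, keepdims=True)
            Sigma_inv = np.linalg.inv(Sigma.Sigma[m])
            S = Sigma_inv @ Y_m
            for k in range(K):
                h = decoupling_vector(W, m, k)
                d = h @ W[k][m]
                if d == 0.0:
                    raise ConvergenceError(f"degenerate demixing matrix at iteration {it}")
                grad = Zc[k] @ S[k] / N - h / d
                w_new = W[k][m] - mu * grad
                nrm = np.linalg.norm(w_new)
                if not np.isfinite(nrm) or nrm == 0.0:
                    raise ConvergenceError(f"divergent row update at iteration {it} (m={m}, k={k})")
                w_new /= nrm
                W[k][m] = w_new
                # refresh the cached component and its score for subsequent rows
                y_new = w_new @ Z[k]
                Y[k, m, :] = y_new
                delta = (y_new - y_new.mean()) - Y_m[k]
                Y_m[k] += delta
                S += np.outer(Sigma_inv[:, k], delta)
        new_cost = _cost_from_components(Y, W)
        if np.isnan(new_cost):
            raise ConvergenceError(f"cost diverged (NaN) at iteration {it}")
        if new_cost > cost or not np.isfinite(new_cost):
            # reject the sweep, shrink the step
            W = W_prev
            Y = Y_prev
            mu *= _ANNEAL
            trajectory.append(cost)
            if mu < _MU_MIN:
                logger.warning("step size underflowed at iteration %d without meeting tol", it)
                break
            continue
        trajectory.append(new_cost)
        if abs(new_cost - cost) < tol:
            cost = new_cost
            converged = True
            break
        cost = new_cost

    return DemixingSet(
        W=W,
        converged=converged,
        n_iter=it,
        cost_trajectory=np.asarray(trajectory),
    )


def joint_isi(W, V=None, A=None) -> float:
    """Normalised joint Amari index of the combined system ``G^[k] = W^[k] V^[k] A^[k]``.

    With ``Gbar_ij = sum_k |G^[k]_ij|`` the index is

        [ sum_i (sum_j Gbar_ij / max_j Gbar_ij - 1)
        + sum_j (sum_i Gbar_ij / max_i Gbar_ij - 1) ] / (2 M (M - 1)),

    which is 0 iff ``Gbar`` is a scaled permutation (all datasets share one
    permutation, i.e. perfect joint separation) and 1 in the fully mixed
    (all-ones) case.  ``V`` may be ``None`` (identity) or per-dataset
    whitening transforms/matrices; likewise ``A``.
    """
    Wmats = W.W if isinstance(W, DemixingSet) else [np.asarray(Wk, dtype=np.float64) for Wk in W]
    K = len(Wmats)
    M = Wmats[0].shape[0]
    if M == 1:
        return 0.0
    G_sum = np.zeros((M, M))
    for k in range(K):
        G = Wmats[k]
        if V is not None:
            Vk = V[k].V if hasattr(V[k], "V") else np.asarray(V[k])
            G = G @ Vk
        if A is not None:
            G = G @ np.asarray(A[k])
        G_sum += np.abs(G)
    row = (G_sum / G_sum.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (G_sum / G_sum.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * M * (M - 1)))
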