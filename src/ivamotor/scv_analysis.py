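"""Cross-subject SCV correlation analysis and initialisation-accuracy densities.

After joint separation, the m-th source component vector (SCV) collects the
m-th component's time series from every subject.  Its K-by-K Pearson
correlation matrix quantifies how strongly the same component co-varies
across subjects; ranking the off-diagonal entries yields, per subject, the
partners and components it shares the most structure with — the raw
material for clustering subjects by motor-imagery response.  The
kernel-density summaries describe how validation accuracy is distributed
over random IVA initialisations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError

__all__ = [
    "CorrelationRecord",
    "DensityCurve",
    "scv_correlation_matrix",
    "top_correlations",
    "kde_accuracy",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationRecord:
    """One ranked cross-subject correlation entry.

    ``component_index`` is the IVA component m, ``subject_pair = (i, j)``
    with ``i`` the subject the table row belongs to, ``value`` the
    fold-averaged Pearson correlation.
    """

    component_index: int
    subject_pair: tuple
    class_label: int
    value: float
    n_folds: int

    def __post_init__(self):
        i, j = self.subject_pair
        if i == j:
            raise DataError("a correlation record pairs two distinct subjects")
        if abs(self.value) > 1 + 1e-12:
            raise DataError(f"correlation {self.value} outside [-1, 1]")


def scv_correlation_matrix(Y, m: int) -> np.ndarray:
    """Pearson correlation of component ``m``'s time series across subjects.

    ``Y`` is K matrices of shape (M, N) (or a (K, M, N) array).  The result
    is symmetric with unit diagonal.  A zero-variance component is an error.
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.ndim != 3:
        raise DataError(f"expected K component matrices (K, M, N), got shape {Y.shape}")
    comp = Y[:, m, :]
    if np.any(comp.std(axis=1) == 0):
        raise DataError(f"component {m} has zero variance for at least one subject")
    C = np.corrcoef(comp)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return C


def top_correlations(fold_matrices, class_label: int, top_n: int = 5):
    """Rank fold-averaged cross-subject correlations per subject.

    Parameters
    ----------
    fold_matrices : array-like of shape (n_folds, M, K, K)
        One K-by-K correlation matrix per component and fold.
    class_label : int
        Class the matrices belong to (tags the records).
    top_n : int
        Entries kept per subject.  If fewer pairs exist, all are returned
        with a logged note.

    Returns
    -------
    dict mapping subject index -> list of :class:`CorrelationRecord`, ranked
    by descending absolute value; ties break to the lower component index,
    then the lower partner index.  The same component or partner may appear
    repeatedly.
    """
    mats = np.asarray(fold_matrices, dtype=np.float64)
    if mats.ndim != 4:
        raise DataError(f"expected (n_folds, M, K, K) fold matrices, got shape {mats.shape}")
    n_folds, M, K, K2 = mats.shape
    if K != K2:
        raise DataError("correlation matrices must be square")
    avg = mats.mean(axis=0)

    out = {}
    for i in range(K):
        candidates = [
            (-abs(avg[m, i, j]), m, j, avg[m, i, j])
            for m in range(M)
            for j in range(K)
            if j != i
        ]
        candidates.sort()
        if top_n > len(candidates):
            logger.info(
                "subject %d: only %d pairs available (top_n=%d); returning all",
                i, len(candidates), top_n,
            )
        out[i] = [
            CorrelationRecord(
                component_index=m,
                subject_pair=(i, j),
                class_label=class_label,
                value=v,
                n_folds=n_folds,
            )
            for _, m, j, v in candidates[:top_n]
        ]
    return out


@dataclass(frozen=True)
class DensityCurve:
    """A density evaluated on a grid over [0, 1]."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def kde_accuracy(accuracies, bandwidth: float | None = None) -> DensityCurve:
    """Gaussian kernel density of accuracies on [0, 1] with boundary reflection.

    Bandwidth defaults to Silverman's rule ``0.9 min(sd, IQR/1.34) n^{-1/5}``.
    Mass that a plain Gaussian kernel would spill past 0 or 1 is reflected
    back, so the curve integrates to 1 over [0, 1] (within quadrature error
    on its evaluation grid).
    """
    a = np.asarray(accuracies, dtype=np.float64).ravel()
    if a.size < 2:
        raise DataError(f"need at least 2 accuracy values for a density, got {a.size}")
    if np.any((a < 0) | (a > 1)):
        raise DataError("accuracies must lie in [0, 1]")
    if bandwidth is None:
        sd = a.std(ddof=1)
        iqr = np.subtract(*np.percentile(a, [75, 25]))
        scale = min(sd, iqr / 1.34) if iqr > 0 else sd
        if scale == 0:
            raise DataError("all accuracies identical; pass an explicit bandwidth")
        bandwidth = 0.9 * scale * a.size ** (-0.2)
    if bandwidth <= 0:
        raise DataError(f"bandwidth must be positive, got {bandwidth}")

    n_grid = int(min(max(512, np.ceil(8.0 / bandwidth)), 2**15))
    grid = np.linspace(0.0, 1.0, n_grid)
    # reflect the sample at both boundaries so no mass escapes [0, 1]
    pts = np.concatenate([a, -a, 2.0 - a])
    diff = (grid[:, None] - pts[None, :]) / bandwidth
    dens = np.exp(-0.5 * diff**2).sum(axis=1) / (a.size * bandwidth * np.sqrt(2.0 * np.pi))
    return DensityCurve(grid=grid, density=dens, bandwidth=float(bandwidth))
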