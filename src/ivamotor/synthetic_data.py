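"""Ground-truth-bearing synthetic inputs for every stage of the pipeline.

Two generators:

* :func:`generate_jbss` — the joint blind source separation model itself:
  K datasets of M Gaussian sources, where source m carries a planted
  compound-symmetric cross-dataset correlation ``rho_m``.  Distinct rho
  values across sources make the model identifiable for IVA-G, so the
  planted mixing matrices are recoverable up to a common permutation,
  scale and sign.

* :func:`generate_two_class_dataset` — a two-class multi-subject
  "EEG-like" trial set.  Latent sources are AR(2) processes whose pole
  (spectral peak) configuration depends on the class, shared in spectral
  shape across subjects; innovations are correlated across subjects
  (inducing cross-subject SCV correlation), mixed per subject, plus white
  sensor noise at a stated SNR.  Emulates the structure of a cue-based
  motor-imagery recording: 2 balanced classes, 4 s trials at 100 Hz.

Both generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .data_model import MultiSubjectDataset, TrialSet
from .exceptions import DataError

__all__ = [
    "JBSSGroundTruth",
    "ARClassSpec",
    "TwoClassGroundTruth",
    "generate_jbss",
    "generate_two_class_dataset",
    "DEFAULT_CLASS_SPECS",
]


@dataclass(frozen=True)
class JBSSGroundTruth:
    """Planted sources, mixings and SCV correlations of a JBSS instance."""

    S: np.ndarray  # (K, M, N) sources
    A: np.ndarray  # (K, M, M) mixing matrices
    rho: np.ndarray  # (M,) cross-dataset correlation per source
    seed: int


def _random_mixing(rng: np.random.Generator, M: int) -> np.ndarray:
    """Random orthogonal matrix times a diagonal scale; condition number <= 9."""
    Q, R = np.linalg.qr(rng.standard_normal((M, M)))
    Q = Q * np.sign(np.diag(R))
    scales = rng.uniform(1.0 / 3.0, 3.0, size=M)
    return Q @ np.diag(scales)


def generate_jbss(K: int, M: int, N: int, rho, seed: int):
    """Draw a JBSS instance ``X^[k] = A^[k] S^[k]`` with planted SCV structure.

    SCV m is i.i.d. over time from a K-variate Gaussian with unit variances
    and compound-symmetric correlation ``rho[m]``.  The rho values must lie
    in [0, 1) and be pairwise distinct by at least 0.05 — identical profiles
    would make the components statistically interchangeable and the joint
    separation unidentifiable.

    Returns
    -------
    X : ndarray (K, M, N)
        Observed mixtures.
    truth : JBSSGroundTruth
    """
    rho = np.asarray(rho, dtype=np.float64)
    if rho.shape != (M,):
        raise DataError(f"rho must have length M={M}, got shape {rho.shape}")
    if np.any(rho < 0) or np.any(rho >= 1):
        raise DataError("each rho_m must lie in [0, 1): compound-symmetric correlation")
    diffs = np.abs(rho[:, None] - rho[None, :])[np.triu_indices(M, 1)]
    if M > 1 and diffs.min() < 0.05:
        raise DataError(
            "rho values must be pairwise distinct by >= 0.05; identical SCV "
            "correlation profiles are unidentifiable for IVA-G"
        )
    rng = np.random.default_rng(seed)
    S = np.empty((K, M, N))
    for m in range(M):
        C = (1.0 - rho[m]) * np.eye(K) + rho[m] * np.ones((K, K))
        L = np.linalg.cholesky(C)
        S[:, m, :] = L @ rng.standard_normal((K, N))
    A = np.stack([_random_mixing(rng, M) for _ in range(K)])
    X = np.einsum("kij,kjn->kin", A, S)
    truth = JBSSGroundTruth(S=S, A=A, rho=rho.copy(), seed=int(seed))
    return X, truth


@dataclass(frozen=True)
class ARClassSpec:
    """Stable AR(2) pole configuration: complex pole pair at ``peak_hz`` with
    modulus ``radius`` (< 1).  The process it defines has a spectral peak
    near ``peak_hz``."""

    peak_hz: float
    radius: float = 0.9

    def coefficients(self, fs: float) -> np.ndarray:
        """AR(2) coefficients (a1, a2) with u(n) = a1 u(n-1) + a2 u(n-2) + e(n)."""
        if not 0 < self.radius < 1:
            raise DataError(f"pole radius {self.radius} is not in (0, 1): unstable AR spec")
        if not 0 < self.peak_hz < fs / 2:
            raise DataError(f"peak {self.peak_hz} Hz outside (0, Nyquist={fs / 2}) band")
        theta = 2.0 * np.pi * self.peak_hz / fs
        return np.array([2.0 * self.radius * np.cos(theta), -self.radius**2])


# mu-band vs beta-band peaks: the two motor-imagery classes differ in which
# sensorimotor rhythm is desynchronised, here idealised as a 10 Hz vs 20 Hz
# spectral peak of the latent sources
DEFAULT_CLASS_SPECS = {1: ARClassSpec(peak_hz=10.0), 2: ARClassSpec(peak_hz=20.0)}


@dataclass(frozen=True)
class TwoClassGroundTruth:
    """Planted structure of a two-class multi-subject trial dataset."""

    A: np.ndarray  # (K, M, M) per-subject mixing
    rho: np.ndarray  # (M,) cross-subject innovation correlation per source
    class_specs: dict
    labels: np.ndarray  # (n_trials,) shared across subjects
    seed: int


def generate_two_class_dataset(
    K: int,
    M: int,
    n_trials_per_class: int,
    T: int = 400,
    fs: float = 100.0,
    class_ar_specs: dict | None = None,
    seed: int = 0,
    mixing_seed: int | None = None,
    noise_snr_db: float = 10.0,
):
    """Generate a two-class multi-subject trial dataset with known structure.

    Per subject and trial, M latent AR(2) sources are driven by innovations
    that are correlated across subjects (compound-symmetric, correlation
    decreasing linearly from 0.9 to 0.1 over sources), filtered with the
    class's pole configuration (each source detuned by a small deterministic
    offset so sources remain spectrally diverse), mixed by a per-subject
    matrix, and summed with white sensor noise at ``noise_snr_db`` (dB of
    per-channel variance ratio).  Labels are balanced, shuffled, and shared
    across subjects.

    Returns
    -------
    ds : MultiSubjectDataset of TrialSets
    truth : TwoClassGroundTruth
    """
    if class_ar_specs is None:
        class_ar_specs = DEFAULT_CLASS_SPECS
    if set(class_ar_specs) != {1, 2}:
        raise DataError("class_ar_specs must map class labels {1, 2} to ARClassSpec")
    if not np.isfinite(noise_snr_db):
        raise DataError("noise SNR must be finite")
    # validate stability up front
    for spec in class_ar_specs.values():
        spec.coefficients(fs)

    rng = np.random.default_rng(seed)
    mix_rng = np.random.default_rng(seed if mixing_seed is None else mixing_seed)
    A = np.stack([_random_mixing(mix_rng, M) for _ in range(K)])
    rho = np.linspace(0.9, 0.1, M)

    n_trials = 2 * n_trials_per_class
    labels = np.repeat([1, 2], n_trials_per_class)
    rng.shuffle(labels)

    # per-source detune keeps sources within a class spectrally distinct
    detune = np.linspace(-2.0, 2.0, M)
    burn = 100
    chol = {}
    for m in range(M):
        C = (1.0 - rho[m]) * np.eye(K) + rho[m] * np.ones((K, K))
        chol[m] = np.linalg.cholesky(C)

    trials = np.empty((K, n_trials, M, T))
    for t, lab in enumerate(labels):
        spec = class_ar_specs[int(lab)]
        S = np.empty((K, M, T))
        for m in range(M):
            e = chol[m] @ rng.standard_normal((K, T + burn))
            a1, a2 = ARClassSpec(
                peak_hz=float(np.clip(spec.peak_hz + detune[m], 1.0, fs / 2 - 1.0)),
                radius=spec.radius,
            ).coefficients(fs)
            u = sps.lfilter([1.0], [1.0, -a1, -a2], e, axis=1)
            S[:, m, :] = u[:, burn:]
        X = np.einsum("kij,kjn->kin", A, S)
        sigma = X.std(axis=2, keepdims=True) * 10.0 ** (-noise_snr_db / 20.0)
        X = X + sigma * rng.standard_normal(X.shape)
        trials[:, t] = X

    channel_names = [f"ch{i:02d}" for i in range(M)]
    subjects = [
        TrialSet(
            trials=trials[k],
            labels=labels.copy(),
            fs=fs,
            channel_names=list(channel_names),
            subject_id=f"sim{k:02d}",
        )
        for k in range(K)
    ]
    ds = MultiSubjectDataset(subjects=subjects)
    truth = TwoClassGroundTruth(
        A=A, rho=rho, class_specs=dict(class_ar_specs), labels=labels, seed=int(seed)
    )
    return ds, truth
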