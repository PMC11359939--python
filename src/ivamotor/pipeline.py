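"""End-to-end class-wise IVA feature-extraction and classification pipeline.

Per cross-validation fold:

1. a stratified hold-out validation set is carved from the training trials;
2. for each of ``n_init`` random initialisations (one standard-normal M-by-M
   matrix shared across subjects and both class runs), IVA-G is fitted
   jointly across subjects on the whitened concatenation of each class's
   training trials, giving per-subject, per-class transforms
   ``(V_c^[k], W_c^[k])``;
3. every trial is mapped through *both* class transforms and the component
   streams stacked (2M channels), AR(q) coefficients are extracted per
   channel, and a per-subject classifier is trained on the training trials
   and scored on the validation trials;
4. the initialisation with the highest mean validation accuracy across
   subjects is selected, and its frozen transforms + classifiers are applied
   to the test trials.

Nothing is ever fitted on validation or test data: whitening, demixing,
feature standardisation and the classifier all use training trials only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline as SkPipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .ar_features import extract_ar_features
from .data_model import (
    ChannelSubset,
    MultiSubjectDataset,
    SubjectRecording,
    TrialSet,
    epoch_trials,
    holdout_split,
    select_channels,
    split_folds,
)
from .exceptions import DataError, IvamotorError
from .iva_g import fit_iva_g
from .preprocessing import apply_whitening, fit_whitening

__all__ = [
    "PipelineConfig",
    "TrainedFold",
    "PipelineReport",
    "train_classwise_iva",
    "transform_trials",
    "classify_train",
    "classify_predict",
    "initialization_search",
    "run_cv_pipeline",
]

logger = logging.getLogger(__name__)

CLASSES = (1, 2)


@dataclass
class PipelineConfig:
    """All knobs of the cross-validated pipeline.

    Defaults follow the study conditions: AR order ``q=4``, initial IVA step
    ``mu=1``, 100 random initialisations, 10-fold cross-validation with a
    10% stratified hold-out for initialisation selection, linear max-margin
    classifier.
    """

    q: int = 4
    mu: float = 1.0
    n_init: int = 100
    kf: int = 10
    holdout_fraction: float = 0.10
    classifier: str = "max_margin"
    classifier_params: dict = field(default_factory=dict)
    channel_subset: ChannelSubset | None = None
    window_s: float = 4.0
    seed: int = 0
    iva_tol: float = 1e-6
    iva_max_iter: int = 512
    per_subject_selection: bool = False

    def __post_init__(self):
        if self.n_init < 1:
            raise DataError(f"n_init must be >= 1, got {self.n_init}")
        if not 0 < self.holdout_fraction < 1:
            raise DataError(f"holdout_fraction must be in (0, 1), got {self.holdout_fraction}")
        if self.kf < 2:
            raise DataError(f"kf must be >= 2, got {self.kf}")
        if self.classifier not in ("max_margin", "nearest_neighbour"):
            raise DataError(f"unknown classifier {self.classifier!r}")


@dataclass
class TrainedFold:
    """Frozen per-class transforms, per-subject classifiers and the search trace."""

    whitening: dict  # class -> list of K WhiteningTransform
    demixing: dict  # class -> list of K (M, M) arrays
    classifiers: list  # K fitted sklearn estimators
    init_accuracies: np.ndarray  # (n_init, K) validation accuracy
    selected_init: int  # argmax of the mean-across-subjects criterion
    n_iter: dict  # class -> iterations of the selected IVA run
    converged: dict  # class -> convergence flag of the selected IVA run
    selected_by_subject: np.ndarray | None = None  # per-subject argmax, if used

    @property
    def mean_init_accuracies(self) -> np.ndarray:
        """Mean validation accuracy across subjects, one entry per initialisation."""
        return self.init_accuracies.mean(axis=1)


@dataclass
class PipelineReport:
    """Per-subject fold accuracies plus the per-fold selection trace."""

    subject_ids: list
    fold_accuracies: np.ndarray  # (K, kf)
    selected_inits: np.ndarray  # (kf,)
    init_accuracies: np.ndarray  # (kf, n_init, K) validation accuracies
    fold_n_iter: list = field(default_factory=list)  # per fold: dict class -> n_iter
    fold_converged: list = field(default_factory=list)
    scv_matrices: dict | None = None  # class -> (kf, M, K, K), optional

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.fold_accuracies.mean(axis=1)

    @property
    def sd_accuracy(self) -> np.ndarray:
        return self.fold_accuracies.std(axis=1, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format report: one row per subject and fold."""
        rows = []
        for i, sid in enumerate(self.subject_ids):
            for f in range(self.fold_accuracies.shape[1]):
                rows.append(
                    dict(
                        subject=sid,
                        fold=f,
                        accuracy=self.fold_accuracies[i, f],
                        selected_init=int(self.selected_inits[f]),
                        n_iter=int(max(self.fold_n_iter[f].values())) if self.fold_n_iter else -1,
                        converged=bool(all(self.fold_converged[f].values())) if self.fold_converged else True,
                    )
                )
        return pd.DataFrame(
            rows, columns=["subject", "fold", "accuracy", "selected_init", "n_iter", "converged"]
        )


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _concat_class_trials(trial_tensors, labels_per_subject, idx_per_subject, cls: int):
    """Per subject, concatenate the class-``cls`` trials at the given indices
    time-wise; truncate to the shortest subject so the joint time axis aligns."""
    mats = []
    for k, (trials, labels, idx) in enumerate(zip(trial_tensors, labels_per_subject, idx_per_subject)):
        sel = idx[labels[idx] == cls]
        if sel.size == 0:
            raise DataError(f"subject index {k} has no trials of class {cls} in this split")
        mats.append(np.concatenate(list(trials[sel]), axis=1))
    n_min = min(m.shape[1] for m in mats)
    return [m[:, :n_min] for m in mats]


def train_classwise_iva(class_data, cfg: PipelineConfig, W_init: np.ndarray):
    """Whiten each subject's class-c data and fit IVA-G jointly across subjects.

    ``class_data`` holds one (M, N) matrix per subject (the time-wise
    concatenation of that subject's class-c training trials, equal N).
    Returns ``(V, demix)``: the per-subject whitening transforms and the
    fitted :class:`~ivamotor.iva_g.DemixingSet`.
    """
    V = []
    for k, X in enumerate(class_data):
        try:
            V.append(fit_whitening(X))
        except IvamotorError as exc:
            raise DataError(f"whitening failed for subject index {k}: {exc}") from exc
    Z = np.stack([apply_whitening(V[k], class_data[k]) for k in range(len(class_data))])
    demix = fit_iva_g(Z, W_init, mu=cfg.mu, tol=cfg.iva_tol, max_iter=cfg.iva_max_iter)
    return V, demix


def transform_trials(trials: np.ndarray, W1, V1, W2, V2) -> np.ndarray:
    """Map one subject's trials through both class transforms and stack.

    ``trials`` is (n, M, T); the output is (n, 2M, T): rows 0..M-1 are the
    class-1 components ``W1 V1 (x - mean1)``, rows M..2M-1 the class-2
    components.  Applied identically to trials of either class — the class
    membership of a test trial is unknown by construction.
    """
    trials = np.asarray(trials, dtype=np.float64)
    if trials.ndim != 3:
        raise DataError(f"trials must be (n, M, T), got shape {trials.shape}")
    if trials.shape[1] != V1.n_channels:
        raise DataError(
            f"trials have {trials.shape[1]} channels, transforms expect {V1.n_channels}"
        )
    y1 = np.einsum("ij,njt->nit", np.asarray(W1), apply_whitening(V1, trials))
    y2 = np.einsum("ij,njt->nit", np.asarray(W2), apply_whitening(V2, trials))
    return np.concatenate([y1, y2], axis=1)


def _make_classifier(cfg: PipelineConfig):
    params = dict(cfg.classifier_params)
    if cfg.classifier == "max_margin":
        clf = SVC(kernel="linear", C=params.pop("C", 1.0), **params)
    else:
        clf = KNeighborsClassifier(n_neighbors=params.pop("k", 5), **params)
    return SkPipeline([("scale", StandardScaler()), ("clf", clf)])


def classify_train(features: np.ndarray, labels: np.ndarray, cfg: PipelineConfig):
    """Fit the configured classifier on standardised features.

    Features are z-scored per dimension with training statistics inside the
    returned sklearn pipeline, so the identical scaling is applied at
    predict time.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise DataError("training set contains a single class; cannot fit a classifier")
    clf = _make_classifier(cfg)
    clf.fit(np.asarray(features), labels)
    return clf


def classify_predict(classifier, features: np.ndarray) -> np.ndarray:
    """Predict class labels for a feature matrix."""
    return classifier.predict(np.asarray(features))


def _features_for_subject(s: TrialSet, idx, transforms, k: int, q: int) -> np.ndarray:
    V1, W1 = transforms[1][0][k], transforms[1][1][k]
    V2, W2 = transforms[2][0][k], transforms[2][1][k]
    y = transform_trials(s.trials[idx], W1, V1, W2, V2)
    return extract_ar_features(y, q=q).matrix


def initialization_search(
    trial_sets,
    train_idx,
    valid_idx,
    cfg: PipelineConfig,
    rng: np.random.Generator,
) -> TrainedFold:
    """Search ``n_init`` random IVA initialisations on validation accuracy.

    Each candidate is a single standard-normal M-by-M matrix shared across
    subjects and both class-wise IVA runs.  The candidate maximising the
    mean validation accuracy across subjects wins; ties go to the lowest
    index.  With ``cfg.per_subject_selection`` each subject instead keeps
    the transforms and classifier of its own best candidate.  All
    per-initialisation accuracies are returned (they feed the KDE
    summaries).  An initialisation whose fit or classifier fails scores 0
    with a warning.
    """
    K = len(trial_sets)
    M = trial_sets[0].n_channels
    train_idx = [np.asarray(ix) for ix in train_idx]
    valid_idx = [np.asarray(ix) for ix in valid_idx]
    for s, ix in zip(trial_sets, valid_idx):
        if ix.size == 0 or any((s.labels[ix] == c).sum() == 0 for c in CLASSES):
            raise DataError(f"subject {s.subject_id!r}: validation set must contain both classes")

    tensors = [s.trials for s in trial_sets]
    labels = [s.labels for s in trial_sets]
    class_data = {c: _concat_class_trials(tensors, labels, train_idx, c) for c in CLASSES}

    accuracies = np.zeros((cfg.n_init, K))
    best = None
    # per-subject best: (accuracy, init index, per-class (V, W) slice, classifier)
    best_subject = [None] * K
    for i in range(cfg.n_init):
        W_init = rng.standard_normal((M, M))
        try:
            transforms = {}
            diag_iter, diag_conv = {}, {}
            for c in CLASSES:
                V, demix = train_classwise_iva(class_data[c], cfg, W_init)
                transforms[c] = (V, demix.W)
                diag_iter[c] = demix.n_iter
                diag_conv[c] = demix.converged
            classifiers = []
            for k, s in enumerate(trial_sets):
                f_train = _features_for_subject(s, train_idx[k], transforms, k, cfg.q)
                clf = classify_train(f_train, s.labels[train_idx[k]], cfg)
                f_valid = _features_for_subject(s, valid_idx[k], transforms, k, cfg.q)
                accuracies[i, k] = np.mean(classify_predict(clf, f_valid) == s.labels[valid_idx[k]])
                classifiers.append(clf)
        except IvamotorError as exc:
            warnings.warn(f"initialisation {i} failed ({exc}); scored 0", stacklevel=2)
            accuracies[i] = 0.0
            continue
        score = accuracies[i].mean()
        if best is None or score > best[0]:
            best = (score, i, transforms, classifiers, diag_iter, diag_conv)
        if cfg.per_subject_selection:
            for k in range(K):
                if best_subject[k] is None or accuracies[i, k] > best_subject[k][0]:
                    slice_k = {c: (transforms[c][0][k], transforms[c][1][k]) for c in CLASSES}
                    best_subject[k] = (accuracies[i, k], i, slice_k, classifiers[k])

    if best is None:
        raise DataError("every initialisation failed")
    _, sel, transforms, classifiers, diag_iter, diag_conv = best
    selected_by_subject = None
    if cfg.per_subject_selection:
        # reassemble per-subject winners into the shared (class -> list over k) layout
        selected_by_subject = np.array([b[1] for b in best_subject])
        transforms = {
            c: ([best_subject[k][2][c][0] for k in range(K)], [best_subject[k][2][c][1] for k in range(K)])
            for c in CLASSES
        }
        classifiers = [best_subject[k][3] for k in range(K)]
    return TrainedFold(
        whitening={c: transforms[c][0] for c in CLASSES},
        demixing={c: transforms[c][1] for c in CLASSES},
        classifiers=classifiers,
        init_accuracies=accuracies,
        selected_init=sel,
        n_iter=diag_iter,
        converged=diag_conv,
        selected_by_subject=selected_by_subject,
    )


# ---------------------------------------------------------------------------
# cross-validated pipeline
# ---------------------------------------------------------------------------

def _as_trial_sets(ds: MultiSubjectDataset, cfg: PipelineConfig):
    if cfg.channel_subset is not None:
        ds = select_channels(ds, cfg.channel_subset)
    out = []
    for s in ds.subjects:
        out.append(epoch_trials(s, cfg.window_s) if isinstance(s, SubjectRecording) else s)
    T0 = out[0].n_samples
    if any(s.n_samples != T0 for s in out):
        raise DataError("subjects disagree on trial length after epoching")
    return out


def run_cv_pipeline(
    ds: MultiSubjectDataset, cfg: PipelineConfig, collect_scv: bool = False
) -> PipelineReport:
    """Run the full k-fold pipeline and aggregate per-subject accuracies.

    Fold splits, hold-out carve-outs and every random initialisation derive
    from ``cfg.seed``, so two runs with the same config and data produce
    identical reports.  With ``collect_scv=True`` the report also carries,
    per class and fold, the cross-subject correlation matrix of every
    component, computed on the matching-class test trials under the
    selected class transform (the input to the SCV correlation tables).
    """
    from .scv_analysis import scv_correlation_matrix  # local import avoids a cycle

    trial_sets = _as_trial_sets(ds, cfg)
    K = len(trial_sets)
    M = trial_sets[0].n_channels

    ss = np.random.SeedSequence(cfg.seed)
    fold_seed, holdout_seed, init_seed = (int(s) for s in ss.generate_state(3) >> np.uint32(1))

    folds_per_subject = [split_folds(s, kf=cfg.kf, seed=fold_seed) for s in trial_sets]

    fold_acc = np.zeros((K, cfg.kf))
    selected = np.zeros(cfg.kf, dtype=int)
    all_init_acc = np.zeros((cfg.kf, cfg.n_init, K))
    fold_n_iter, fold_converged = [], []
    scv = {c: [] for c in CLASSES} if collect_scv else None

    for f in range(cfg.kf):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=init_seed, spawn_key=(f,)))
        train_idx, valid_idx, test_idx = [], [], []
        for k, s in enumerate(trial_sets):
            tr_all, te = folds_per_subject[k][f]
            tr, va = holdout_split(s, tr_all, fraction=cfg.holdout_fraction, seed=holdout_seed + f)
            train_idx.append(tr)
            valid_idx.append(va)
            test_idx.append(te)
        try:
            fold = initialization_search(trial_sets, train_idx, valid_idx, cfg, rng)
        except IvamotorError as exc:
            raise DataError(f"fold {f}: {exc}") from exc
        selected[f] = fold.selected_init
        all_init_acc[f] = fold.init_accuracies
        fold_n_iter.append(fold.n_iter)
        fold_converged.append(fold.converged)

        transforms = {c: (fold.whitening[c], fold.demixing[c]) for c in CLASSES}
        for k, s in enumerate(trial_sets):
            f_test = _features_for_subject(s, test_idx[k], transforms, k, cfg.q)
            pred = classify_predict(fold.classifiers[k], f_test)
            fold_acc[k, f] = np.mean(pred == s.labels[test_idx[k]])

        if collect_scv:
            for c in CLASSES:
                comps = [
                    np.einsum(
                        "ij,njt->nit",
                        np.asarray(fold.demixing[c][k]),
                        apply_whitening(fold.whitening[c][k], trial_sets[k].trials),
                    )
                    for k in range(K)
                ]
                comp = _concat_class_trials(
                    comps, [s.labels for s in trial_sets], test_idx, c
                )
                mats = np.stack([scv_correlation_matrix(np.stack(comp), m) for m in range(M)])
                scv[c].append(mats)
        logger.info("fold %d/%d done: mean test accuracy %.3f", f + 1, cfg.kf, fold_acc[:, f].mean())

    return PipelineReport(
        subject_ids=[s.subject_id or f"subject{k:02d}" for k, s in enumerate(trial_sets)],
        fold_accuracies=fold_acc,
        selected_inits=selected,
        init_accuracies=all_init_acc,
        fold_n_iter=fold_n_iter,
        fold_converged=fold_converged,
        scv_matrices={c: np.stack(scv[c]) for c in CLASSES} if collect_scv else None,
    )
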