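"""Domain types and IO for multi-subject motor-imagery EEG.

Covers the on-disk dialects (the BCI Competition III dataset 4a MAT layout
and a neutral HDF5 container), cue-based trial epoching, channel-subset
selection, and stratified fold / hold-out splitting.

Conventions: sample indices are 0-based; trial windows are half-open
``[pos, pos + window_s * fs)`` starting at the cue onset; class labels are
``1 = right hand``, ``2 = right foot``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.io
from sklearn.model_selection import StratifiedKFold, train_test_split

from .exceptions import DataError, FormatError

__all__ = [
    "SubjectRecording",
    "TrialSet",
    "MultiSubjectDataset",
    "ChannelSubset",
    "FRONTAL_37",
    "load_ds4a_mat",
    "load_hdf5",
    "save_hdf5",
    "epoch_trials",
    "select_channels",
    "split_folds",
    "holdout_split",
]

logger = logging.getLogger(__name__)

VALID_LABELS = frozenset({1, 2})

# Fronto-central montage (extended 10-20 labels) known for strong activity
# during hand/foot motor imagery; the subset that performed best in the
# channel-count study this package accompanies.
FRONTAL_37_CHANNELS = (
    "FAF5", "FAF1", "FAF2", "FAF6",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FFC7", "FFC5", "FFC1", "FFC2", "FFC4", "FFC6", "FFC8",
    "FT9", "FT7", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "CFC7", "CFC5", "CFC3", "CFC1", "CFC2", "CFC4", "CFC6",
)

# integer-to-microvolt scaling of the 100 Hz competition release
DS4A_UV_PER_LSB = 0.1


def _check_labels(labels: np.ndarray) -> None:
    bad = set(np.unique(labels)) - VALID_LABELS
    if bad:
        raise DataError(f"labels must be 1 (right hand) or 2 (right foot); found {sorted(bad)}")


@dataclass
class SubjectRecording:
    """A continuous multichannel recording with cue markers and class labels.

    ``data`` is channels-by-samples in microvolts; ``marker_positions`` are
    0-based cue-onset sample indices, one label per marker.
    """

    subject_id: str
    data: np.ndarray
    fs: float
    channel_names: list[str]
    marker_positions: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.marker_positions = np.asarray(self.marker_positions, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 2:
            raise DataError(f"data must be (channels, samples); got shape {self.data.shape}")
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise DataError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} data rows"
            )
        if self.labels.shape != self.marker_positions.shape:
            raise DataError("labels and marker_positions must have equal length")
        if self.labels.size:
            _check_labels(self.labels)
        if np.any(self.marker_positions < 0) or np.any(self.marker_positions >= self.data.shape[1]):
            raise DataError("marker positions must lie within the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialSet:
    """Epoched trials: ``trials`` is (n_trials, channels, samples-per-trial)."""

    trials: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str = ""

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.trials.ndim != 3:
            raise DataError(f"trials must be (n_trials, channels, T); got shape {self.trials.shape}")
        if self.labels.shape[0] != self.trials.shape[0]:
            raise DataError("one label per trial required")
        if len(self.channel_names) != self.trials.shape[1]:
            raise DataError("channel_names length must match trial channel count")
        if self.labels.size:
            _check_labels(self.labels)

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    def subset(self, idx) -> "TrialSet":
        """Trials at the given indices, order preserved."""
        idx = np.asarray(idx)
        return TrialSet(
            trials=self.trials[idx],
            labels=self.labels[idx],
            fs=self.fs,
            channel_names=list(self.channel_names),
            subject_id=self.subject_id,
        )


@dataclass
class MultiSubjectDataset:
    """An ordered collection of K >= 2 subjects sharing montage and timing."""

    subjects: list

    def __post_init__(self):
        if len(self.subjects) < 2:
            raise DataError(f"need at least 2 subjects for joint separation, got {len(self.subjects)}")
        first = self.subjects[0]
        for s in self.subjects[1:]:
            if s.n_channels != first.n_channels:
                raise DataError("all subjects must share the channel count")
            if s.fs != first.fs:
                raise DataError("all subjects must share the sampling rate")
            if list(s.channel_names) != list(first.channel_names):
                raise DataError("all subjects must share channel names and order")
            if isinstance(s, TrialSet) and isinstance(first, TrialSet):
                if s.n_samples != first.n_samples:
                    raise DataError("all subjects must share the trial length T")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_channels(self) -> int:
        return self.subjects[0].n_channels

    @property
    def fs(self) -> float:
        return self.subjects[0].fs


@dataclass(frozen=True)
class ChannelSubset:
    """A named, ordered, duplicate-free list of channel names."""

    name: str
    channels: tuple

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))
        if len(set(self.channels)) != len(self.channels):
            raise DataError(f"channel subset {self.name!r} contains duplicates")


FRONTAL_37 = ChannelSubset(name="frontal37", channels=FRONTAL_37_CHANNELS)


# ---------------------------------------------------------------------------
# MAT dialect of BCI Competition III dataset 4a (100 Hz release)
# ---------------------------------------------------------------------------

def _mat_field(mat: dict, name: str, path: str):
    if name not in mat:
        raise FormatError(f"{path}: missing required MAT field {name!r}")
    return mat[name]


def load_ds4a_mat(path) -> SubjectRecording:
    """Read one subject of the competition's 100 Hz MAT release.

    The file stores the continuous signal ``cnt`` as int16 in units of
    0.1 microvolt, marker positions and classes under ``mrk``, and the
    channel labels and sampling rate under ``nfo``.  Markers whose class is
    undefined (the competition's held-back test trials) are dropped with a
    logged count.
    """
    path = str(path)
    mat = scipy.io.loadmat(path, squeeze_me=True, struct_as_record=False)
    cnt = np.asarray(_mat_field(mat, "cnt", path))
    mrk = _mat_field(mat, "mrk", path)
    nfo = _mat_field(mat, "nfo", path)
    for obj, fields, group in ((mrk, ("pos", "y"), "mrk"), (nfo, ("fs", "clab"), "nfo")):
        for f in fields:
            if not hasattr(obj, f):
                raise FormatError(f"{path}: missing required MAT field {group}.{f!r}")

    data = cnt.astype(np.float64).T * DS4A_UV_PER_LSB  # stored samples x channels
    if not np.all(np.isfinite(data)):
        raise DataError(f"{path}: continuous signal contains non-finite samples")

    fs = float(np.asarray(nfo.fs).squeeze())
    clab = [str(c) for c in np.atleast_1d(nfo.clab)]
    pos = np.atleast_1d(np.asarray(mrk.pos)).astype(np.float64)
    y = np.atleast_1d(np.asarray(mrk.y)).astype(np.float64)
    labeled = np.isfinite(y)
    n_dropped = int((~labeled).sum())
    if n_dropped:
        logger.info("%s: dropped %d unlabeled (competition test) markers", path, n_dropped)
    # positions are 1-based sample indices in the source files
    positions = pos[labeled].astype(np.int64) - 1
    labels = y[labeled].astype(np.int64)

    subject_id = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return SubjectRecording(
        subject_id=subject_id,
        data=data,
        fs=fs,
        channel_names=clab,
        marker_positions=positions,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Neutral HDF5 container
# ---------------------------------------------------------------------------

def save_hdf5(ds: MultiSubjectDataset, path) -> None:
    """Write a dataset to ``/subjects/<id>/{data,fs,channel_names,marker_positions,labels}``.

    Trial sets store their tensor under ``data`` with an attribute marking
    the epoched layout.  Subject order is preserved in a root attribute.
    """
    with h5py.File(path, "w") as f:
        root = f.create_group("subjects")
        order = []
        for s in ds.subjects:
            sid = s.subject_id or f"subject{len(order):02d}"
            order.append(sid)
            g = root.create_group(sid)
            g.create_dataset("data", data=(s.trials if isinstance(s, TrialSet) else s.data))
            g.attrs["epoched"] = isinstance(s, TrialSet)
            g.create_dataset("fs", data=float(s.fs))
            g.create_dataset(
                "channel_names",
                data=np.array([c.encode() for c in s.channel_names]),
            )
            if isinstance(s, TrialSet):
                g.create_dataset("marker_positions", data=np.empty(0, dtype=np.int64))
                g.create_dataset("labels", data=s.labels)
            else:
                g.create_dataset("marker_positions", data=s.marker_positions)
                g.create_dataset("labels", data=s.labels)
        f.attrs["subject_order"] = [sid.encode() for sid in order]


def load_hdf5(path) -> MultiSubjectDataset:
    """Read a dataset written by :func:`save_hdf5` (lossless round-trip)."""
    with h5py.File(path, "r") as f:
        if "subjects" not in f:
            raise FormatError(f"{path}: missing /subjects group")
        root = f["subjects"]
        order = [s.decode() if isinstance(s, bytes) else str(s) for s in f.attrs.get("subject_order", list(root))]
        if not order:
            raise FormatError(f"{path}: no subjects")
        subjects = []
        for sid in order:
            if sid not in root:
                raise FormatError(f"{path}: subject_order names missing group {sid!r}")
            g = root[sid]
            for req in ("data", "fs", "channel_names", "marker_positions", "labels"):
                if req not in g:
                    raise FormatError(f"{path}: /subjects/{sid} missing {req!r}")
            names = [c.decode() if isinstance(c, bytes) else str(c) for c in g["channel_names"][()]]
            common = dict(
                subject_id=sid,
                fs=float(g["fs"][()]),
                channel_names=names,
            )
            if g.attrs.get("epoched", False):
                subjects.append(TrialSet(trials=g["data"][()], labels=g["labels"][()], **common))
            else:
                subjects.append(
                    SubjectRecording(
                        data=g["data"][()],
                        marker_positions=g["marker_positions"][()],
                        labels=g["labels"][()],
                        **common,
                    )
                )
    return MultiSubjectDataset(subjects=subjects)


# ---------------------------------------------------------------------------
# Epoching, channel selection, splitting
# ---------------------------------------------------------------------------

def epoch_trials(rec: SubjectRecording, window_s: float = 4.0) -> TrialSet:
    """Cut one trial per cue marker: samples ``[pos, pos + window_s * fs)``.

    The window starts at the cue onset.  Markers whose window would overrun
    the recording are dropped with a logged warning rather than zero-padded
    (padding would bias the trial's autocovariance, hence its AR features).
    """
    T_float = window_s * rec.fs
    T = int(round(T_float))
    if T <= 0 or abs(T_float - T) > 1e-9:
        raise DataError(f"window_s * fs must be a positive integer, got {T_float}")
    keep = rec.marker_positions + T <= rec.n_samples
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d trials whose %g s window overruns the recording",
            rec.subject_id, n_dropped, window_s,
        )
    positions = rec.marker_positions[keep]
    trials = np.stack([rec.data[:, p : p + T] for p in positions]) if positions.size else np.empty((0, rec.n_channels, T))
    return TrialSet(
        trials=trials,
        labels=rec.labels[keep],
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        subject_id=rec.subject_id,
    )


def select_channels(ds: MultiSubjectDataset, subset: ChannelSubset) -> MultiSubjectDataset:
    """Restrict every subject to the subset's channels, in subset order."""
    names = ds.subjects[0].channel_names
    index = {c: i for i, c in enumerate(names)}
    missing = [c for c in subset.channels if c not in index]
    if missing:
        raise DataError(f"channel subset {subset.name!r} names unknown channels: {missing}")
    idx = [index[c] for c in subset.channels]
    out = []
    for s in ds.subjects:
        if isinstance(s, TrialSet):
            out.append(
                TrialSet(
                    trials=s.trials[:, idx, :],
                    labels=s.labels,
                    fs=s.fs,
                    channel_names=list(subset.channels),
                    subject_id=s.subject_id,
                )
            )
        else:
            out.append(
                SubjectRecording(
                    subject_id=s.subject_id,
                    data=s.data[idx, :],
                    fs=s.fs,
                    channel_names=list(subset.channels),
                    marker_positions=s.marker_positions,
                    labels=s.labels,
                )
            )
    return MultiSubjectDataset(subjects=out)


def split_folds(trials: TrialSet, kf: int = 10, seed: int = 0):
    """Stratified k-fold split of a trial set.

    Returns a list of ``(train_idx, test_idx)`` integer-array pairs that
    partition all trials; each class must have at least ``kf`` trials.
    Deterministic given ``seed``.
    """
    if kf < 2:
        raise DataError(f"kf must be >= 2 to form a test partition, got {kf}")
    labels = trials.labels
    for c in np.unique(labels):
        n_c = int((labels == c).sum())
        if n_c < kf:
            raise DataError(f"class {c} has only {n_c} trials; needs >= kf={kf}")
    skf = StratifiedKFold(n_splits=kf, shuffle=True, random_state=int(seed) % (2**32))
    return [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def holdout_split(trials: TrialSet, train_idx=None, fraction: float = 0.10, seed: int = 0):
    """Carve a class-stratified validation set out of training indices.

    ``train_idx`` defaults to all trials.  Returns ``(train, validation)``
    index arrays; deterministic given ``seed``.
    """
    if not 0 < fraction < 1:
        raise DataError(f"hold-out fraction must be in (0, 1), got {fraction}")
    if train_idx is None:
        train_idx = np.arange(trials.n_trials)
    train_idx = np.asarray(train_idx)
    labels = trials.labels[train_idx]
    n_classes = np.unique(labels).size
    # at least one validation trial per class, whatever the fraction implies
    n_va = max(int(np.ceil(fraction * len(train_idx))), n_classes)
    if n_va >= len(train_idx):
        raise DataError(f"hold-out of {n_va} trials would exhaust the {len(train_idx)} training trials")
    tr, va = train_test_split(
        train_idx,
        test_size=n_va,
        stratify=labels,
        random_state=int(seed) % (2**32),
    )
    return np.sort(tr), np.sort(va)
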