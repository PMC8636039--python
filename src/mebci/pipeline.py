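"""Classification stage: preprocessing, CSP features, classifiers, comparison.

Implements the application pipeline: detrend + 2–55 Hz zero-phase Butterworth
filtering, 100 ms windowing, one-vs-rest common-spatial-pattern features
(log-variance of m retained filter pairs per class), a bank of standard
classifiers with stratified 5-fold validation, session-disjoint testing, and
the augmented-vs-real comparison with per-classifier accuracy deltas and a
two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg as sla
from scipy import signal as sig
from scipy import stats

__all__ = [
    "CLASSES",
    "TrialSet",
    "SpatialFilterBank",
    "WindowBatch",
    "ClassificationReport",
    "preprocess",
    "slice_windows",
    "csp_fit",
    "csp_features",
    "default_classifiers",
    "train_and_validate",
    "fit_models",
    "evaluate_test",
    "compare_conditions",
]

CLASSES = ("mRB", "mFB", "mLS", "mRS")


@dataclass(frozen=True)
class TrialSet:
    """Labeled multichannel EEG trials.

    data: (trials, samples, channels) in microvolt-scale units.
    """

    data: np.ndarray
    labels: tuple[str, ...]
    fs: float
    session_ids: tuple[int, ...]
    subject: str = ""
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "session_ids", tuple(int(s) for s in self.session_ids))
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if d.ndim != 3:
            raise ValueError("data must be (trials, samples, channels)")
        if len(self.labels) != d.shape[0] or len(self.session_ids) != d.shape[0]:
            raise ValueError("labels/session_ids must match trial count")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.channel_names and len(self.channel_names) != d.shape[2]:
            raise ValueError("channel_names must match channel count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def select(self, mask) -> "TrialSet":
        mask = np.asarray(mask)
        idx = np.where(mask)[0] if mask.dtype == bool else mask
        return replace(
            self,
            data=self.data[idx],
            labels=tuple(self.labels[i] for i in idx),
            session_ids=tuple(self.session_ids[i] for i in idx),
        )

    def concat(self, other: "TrialSet") -> "TrialSet":
        if other.n_channels != self.n_channels or other.fs != self.fs:
            raise ValueError("incompatible trial sets")
        return replace(
            self,
            data=np.concatenate([self.data, other.data], axis=0),
            labels=self.labels + other.labels,
            session_ids=self.session_ids + other.session_ids,
        )


@dataclass(frozen=True)
class WindowBatch:
    """Short windows with per-window class labels (and one-hot view)."""

    windows: np.ndarray  # (n, window_len, channels)
    labels: tuple[str, ...]
    fs: float
    source: str = "real"  # "real" | "fake"
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        w = np.asarray(self.windows, dtype=float)
        object.__setattr__(self, "windows", w)
        object.__setattr__(self, "labels", tuple(self.labels))
        if w.ndim != 3 or len(self.labels) != w.shape[0]:
            raise ValueError("windows must be (n, len, channels) with matching labels")

    @property
    def one_hot(self) -> np.ndarray:
        idx = np.array([self.classes.index(l) for l in self.labels])
        out = np.zeros((len(idx), len(self.classes)))
        out[np.arange(len(idx)), idx] = 1.0
        return out

    @property
    def y(self) -> np.ndarray:
        return np.array([self.classes.index(l) for l in self.labels])

    def concat(self, other: "WindowBatch") -> "WindowBatch":
        return replace(
            self,
            windows=np.concatenate([self.windows, other.windows], axis=0),
            labels=self.labels + other.labels,
            source="mixed" if self.source != other.source else self.source,
        )


@dataclass(frozen=True)
class SpatialFilterBank:
    """Per-class one-vs-rest CSP projections, rows sorted by eigenvalue."""

    filters: dict[str, np.ndarray]  # class -> (channels, channels)
    eigenvalues: dict[str, np.ndarray]
    m: int  # retained filter pairs

    def __post_init__(self) -> None:
        for w in self.filters.values():
            if self.m > w.shape[0] // 2:
                raise ValueError("m must be <= channels/2")


@dataclass(frozen=True)
class ClassificationReport:
    condition: str  # "real_only" | "augmented"
    validation_accuracy: dict[str, float]  # percent
    test_accuracy: dict[str, float]  # percent
    confusion: dict[str, np.ndarray]  # (4, 4), rows = true class
    classes: tuple[str, ...] = CLASSES
    notes: dict[str, str] = field(default_factory=dict)


def preprocess(ts: TrialSet, band=(2.0, 55.0), order: int = 4) -> TrialSet:
    """Per-trial/channel linear detrend then zero-phase Butterworth band-pass."""
    if ts.fs <= 2 * band[1]:
        raise ValueError(f"fs={ts.fs} too low for band {band}")
    x = sig.detrend(ts.data, axis=1, type="linear")
    sos = sig.butter(order, band, btype="bandpass", fs=ts.fs, output="sos")
    y = sig.sosfiltfilt(sos, x, axis=1)
    y = y - y.mean(axis=1, keepdims=True)  # edge transients leave residual DC
    return replace(ts, data=y)


def slice_windows(ts: TrialSet, window_len: int, stride: int | None = None,
                  source: str = "real") -> WindowBatch:
    """Slice every trial into windows (non-overlapping by default)."""
    if window_len > ts.data.shape[1]:
        raise ValueError("window_len exceeds trial length")
    stride = window_len if stride is None else stride
    starts = range(0, ts.data.shape[1] - window_len + 1, stride)
    wins, labs = [], []
    for t in range(ts.n_trials):
        for s in starts:
            wins.append(ts.data[t, s: s + window_len, :])
            labs.append(ts.labels[t])
    return WindowBatch(np.stack(wins), tuple(labs), ts.fs, source=source)


def _normalized_cov(w: np.ndarray, shrink: float = 1e-6) -> np.ndarray:
    w = w - w.mean(axis=0, keepdims=True)
    c = w.T @ w
    tr = np.trace(c)
    if tr <= 0:
        tr = 1.0
    c = c / tr
    return c + shrink * np.eye(c.shape[0])


def csp_fit(wb: WindowBatch, m: int = 3) -> SpatialFilterBank:
    """One-vs-rest CSP: generalized eigendecomposition of (S_c, S_c + S_rest).

    Covariances are per-window spatial covariances normalized by trace and
    averaged within class; a small ridge keeps them full rank. Eigenvectors
    are sorted by decreasing eigenvalue and sign-fixed so the largest-
    magnitude coefficient is positive.
    """
    classes = sorted(set(wb.labels))
    counts = {c: wb.labels.count(c) for c in classes}
    if any(v < 2 for v in counts.values()):
        raise ValueError("need at least 2 windows per class")
    covs = {
        c: np.mean(
            [_normalized_cov(w) for w, l in zip(wb.windows, wb.labels) if l == c],
            axis=0,
        )
        for c in classes
    }
    filters, eigs = {}, {}
    for c in classes:
        s_c = covs[c]
        s_rest = np.mean([covs[o] for o in classes if o != c], axis=0)
        vals, vecs = sla.eigh(s_c, s_c + s_rest)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        w = vecs.T  # rows are spatial filters
        flip = np.sign(w[np.arange(len(w)), np.argmax(np.abs(w), axis=1)])
        w = w * flip[:, None]
        filters[c], eigs[c] = w, vals
    return SpatialFilterBank(filters, eigs, m)


def csp_features(wb: WindowBatch, bank: SpatialFilterBank,
                 eps: float = 1e-12) -> np.ndarray:
    """Log-variance features: 2m per class bank, concatenated."""
    feats = []
    for c in sorted(bank.filters):
        w = bank.filters[c]
        if w.shape[1] != wb.windows.shape[2]:
            raise ValueError("channel count mismatch between windows and bank")
        sel = np.concatenate([w[: bank.m], w[-bank.m:]], axis=0)
        proj = np.einsum("fc,ntc->nft", sel, wb.windows)
        var = proj.var(axis=2)
        feats.append(np.log(np.maximum(var, eps)))
    return np.concatenate(feats, axis=1)


def default_classifiers(seed: int = 0) -> dict:
    """Classifier families mirroring the evaluated set (framework defaults)."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return {
        "fine_knn": KNeighborsClassifier(n_neighbors=1),
        "medium_knn": KNeighborsClassifier(n_neighbors=10),
        "cosine_knn": KNeighborsClassifier(n_neighbors=10, metric="cosine"),
        "tree": DecisionTreeClassifier(random_state=seed),
        "linear_svm": SVC(kernel="linear", random_state=seed),
        "gaussian_svm": SVC(kernel="rbf", random_state=seed),
        "lda": LinearDiscriminantAnalysis(),
        "bagged_trees": RandomForestClassifier(
            n_estimators=30, random_state=seed
        ),
        "subspace_knn": BaggingClassifier(
            KNeighborsClassifier(n_neighbors=1),
            n_estimators=10,
            max_features=0.5,
            random_state=seed,
        ),
    }


def train_and_validate(features: np.ndarray, y: np.ndarray, classifiers: dict,
                       n_folds: int = 5, seed: int = 0) -> dict[str, float]:
    """Stratified k-fold validation accuracy (percent) per classifier."""
    from sklearn.base import clone
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(f"every class needs >= {n_folds} windows")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return {
        name: float(100.0 * cross_val_score(clone(est), features, y, cv=skf).mean())
        for name, est in classifiers.items()
    }


def fit_models(features: np.ndarray, y: np.ndarray, classifiers: dict) -> dict:
    from sklearn.base import clone

    return {name: clone(est).fit(features, y) for name, est in classifiers.items()}


def evaluate_test(
    models: dict,
    test_features: np.ndarray,
    y_test: np.ndarray,
    validation_accuracy: dict[str, float],
    condition: str,
    classes=CLASSES,
) -> ClassificationReport:
    """Test accuracy and confusion matrix (rows = true class) per classifier."""
    from sklearn.metrics import confusion_matrix

    test_acc, confusion = {}, {}
    label_ids = np.arange(len(classes))
    for name, model in models.items():
        pred = model.predict(test_features)
        test_acc[name] = float(100.0 * np.mean(pred == y_test))
        confusion[name] = confusion_matrix(y_test, pred, labels=label_ids)
    notes = {
        name: "validation below 90%"
        for name, acc in validation_accuracy.items()
        if acc < 90.0
    }
    return ClassificationReport(
        condition, dict(validation_accuracy), test_acc, confusion, tuple(classes),
        notes,
    )


def compare_conditions(rep_aug: ClassificationReport,
                       rep_real: ClassificationReport) -> dict:
    """Signed per-classifier deltas (augmented - real) and a two-sample t-test."""
    if set(rep_aug.test_accuracy) != set(rep_real.test_accuracy):
        raise ValueError("classifier sets differ between reports")
    names = sorted(rep_aug.test_accuracy)
    deltas = {
        n: rep_aug.test_accuracy[n] - rep_real.test_accuracy[n] for n in names
    }
    dv = np.array([deltas[n] for n in names])
    pooled_aug = [rep_aug.validation_accuracy[n] for n in names] + [
        rep_aug.test_accuracy[n] for n in names
    ]
    pooled_real = [rep_real.validation_accuracy[n] for n in names] + [
        rep_real.test_accuracy[n] for n in names
    ]
    if np.var(pooled_aug) == 0 and np.var(pooled_real) == 0:
        t_stat, p_value = 0.0, 1.0  # degenerate: identical constant samples
    else:
        t_stat, p_value = stats.ttest_ind(pooled_aug, pooled_real)
    return {
        "deltas": deltas,
        "mean_delta": float(dv.mean()),
        "sd_delta": float(dv.std(ddof=1)) if len(dv) > 1 else 0.0,
        "t_statistic": float(t_stat),
        "p_value": float(p_value),
    }
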