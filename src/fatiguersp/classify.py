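"""Fatigue-level classification from single-trial ERSP features.

Each trial contributes a 12-dimensional feature vector: the single-trial
gain-model ERSP (dB against the subject's common baseline), averaged over
the task window and band, for six motor channels (FC3, C1, C3, C5, CP1,
CP3) x two bands (alpha, beta).  Trials are pooled across subjects and
classified with a linear SVM (C = 1, no tuning) under stratified k-fold
cross-validation; features are standardised with training-fold statistics
only.  A subject-grouped CV mode is available for leakage-aware evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import (
    GroupKFold,
    StratifiedKFold,
    cross_val_predict,
)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import (
    CONDITIONS,
    MOTOR_CHANNELS,
    UNASSIGNED,
    BaselineSpectrum,
    ConfigurationError,
    StructureError,
    TFPower,
)
from .ersp import TASK_WINDOWS, _window_mask, band_average

#: Bands used for the per-trial feature vector.
FEATURE_BANDS = {"alpha": (8.0, 13.0), "beta": (13.0, 30.0)}


@dataclass
class FeatureTable:
    """Per-trial ERSP features with labels and subject provenance."""

    features: np.ndarray
    columns: list[str]
    label: np.ndarray
    subject_id: np.ndarray
    window_kind: str

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.label = np.asarray(self.label, dtype=object)
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        if self.features.ndim != 2:
            raise StructureError("features must be trials x columns")
        if self.features.shape[1] != len(self.columns):
            raise StructureError("column names do not match feature width")
        if np.any(~np.isfinite(self.features)):
            raise StructureError("features contain missing values")

    @property
    def n_trials(self) -> int:
        return self.features.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.columns)
        df.insert(0, "subject", self.subject_id)
        df.insert(1, "label", self.label)
        return df


def build_features(tfs: dict[str, TFPower],
                   baselines: dict[str, BaselineSpectrum],
                   window_kind: str = "steady",
                   bands: dict[str, tuple[float, float]] | None = None,
                   channels=MOTOR_CHANNELS) -> FeatureTable:
    """Single-trial ERSP features for one subject (channels x bands).

    Per selected trial, channel and band: 10 log10(trial power / B_AVG)
    averaged over the valid task-window time points and band frequencies.
    Column order is channel-major: (ch1, band1), (ch1, band2), (ch2, band1)...
    """
    if bands is None:
        bands = FEATURE_BANDS
    missing = [ch for ch in channels if ch not in tfs]
    if missing:
        raise StructureError(f"missing channel decompositions: {missing}")
    window = TASK_WINDOWS[window_kind]

    first = tfs[channels[0]]
    selected = np.flatnonzero(first.condition != UNASSIGNED)
    if len(selected) == 0:
        raise StructureError("no condition-labelled trials")

    cols, feats = [], []
    for ch in channels:
        tf, base = tfs[ch], baselines[ch]
        if not np.array_equal(tf.condition, first.condition):
            raise StructureError("channels disagree on trial labels")
        mask = _window_mask(tf, window)
        db = 10.0 * np.log10(tf.power[selected] / base.b_avg[None, :, None])
        # mean over valid window time points, per frequency
        vec = np.stack([
            db[:, i, mask[i]].mean(axis=1) for i in range(len(tf.freqs))
        ], axis=1)  # trials x freqs
        for bname, bedges in bands.items():
            cols.append(f"{ch}_{bname}")
            feats.append(band_average(vec, tf.freqs, bedges))
    return FeatureTable(
        features=np.stack(feats, axis=1), columns=cols,
        label=first.condition[selected].copy(),
        subject_id=np.full(len(selected), first.subject_id, dtype=object),
        window_kind=window_kind,
    )


def concat_features(tables: list[FeatureTable]) -> FeatureTable:
    """Pool per-subject feature tables across the cohort."""
    if not tables:
        raise StructureError("no feature tables to concatenate")
    cols = tables[0].columns
    if any(t.columns != cols for t in tables):
        raise StructureError("feature tables have mismatched columns")
    return FeatureTable(
        features=np.concatenate([t.features for t in tables]),
        columns=cols,
        label=np.concatenate([t.label for t in tables]),
        subject_id=np.concatenate([t.subject_id for t in tables]),
        window_kind=tables[0].window_kind,
    )


@dataclass
class ClassificationResult:
    """Cross-validated accuracy (%) and fold-summed confusion matrix."""

    accuracy: float
    confusion: pd.DataFrame
    classes: tuple[str, ...]
    folds: int
    seed: int

    def __str__(self) -> str:
        return (f"{len(self.classes)}-class linear SVM, "
                f"{self.folds}-fold CV: accuracy {self.accuracy:.2f} %\n"
                f"{self.confusion}")


def crossvalidate_svm(features: FeatureTable,
                      classes=CONDITIONS,
                      folds: int = 10, seed: int = 0,
                      grouped: bool = False) -> ClassificationResult:
    """Linear-SVM cross-validation over the requested fatigue classes.

    Stratified k-fold (shuffled with ``seed``) by default, or grouped by
    subject with ``grouped=True``.  The SVM uses a linear kernel with the
    default regularisation C = 1; features are standardised inside each
    training fold.  Returns overall accuracy (%) and the classes x classes
    confusion matrix summed over folds.
    """
    classes = tuple(classes)
    keep = np.isin(features.label, classes)
    X, y = features.features[keep], features.label[keep].astype(str)
    groups = features.subject_id[keep]
    counts = {c: int(np.sum(y == c)) for c in classes}
    absent = [c for c, n in counts.items() if n == 0]
    if absent:
        raise StructureError(f"classes absent from the data: {absent}")
    if min(counts.values()) < folds and not grouped:
        raise ConfigurationError(
            f"need >= {folds} trials per class, have {counts}"
        )

    model = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    if grouped:
        cv = GroupKFold(n_splits=folds)
        pred = cross_val_predict(model, X, y, cv=cv, groups=groups)
    else:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        pred = cross_val_predict(model, X, y, cv=cv)
    cm = confusion_matrix(y, pred, labels=list(classes))
    acc = 100.0 * np.trace(cm) / cm.sum()
    confusion = pd.DataFrame(cm, index=list(classes),
                             columns=[f"pred_{c}" for c in classes])
    return ClassificationResult(
        accuracy=float(acc), confusion=confusion, classes=classes,
        folds=folds, seed=seed,
    )
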