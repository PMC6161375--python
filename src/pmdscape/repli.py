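"""Replication-timing classes of PMDs and their histone-mark classifier.

PMDs are profiled against the six Repli-seq phase signals (G1, S1-S4, G2)
in scale-regions layout, clustered by k-means into three classes named by
their late-phase signal (early/mid S, mid/late S, late S/G2), and the
classes are then re-predicted from broad histone marks (H3K27me3, H3K9me3,
H3K36me3) with a random forest selected by repeated cross-validation.
Accuracy is reported one-vs-all, averaged over the three classes, on a
held-out 25% split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold, train_test_split

from pmdscape.core_io import SegmentSet, SignalTrack
from pmdscape.profiles import scale_regions_matrix

logger = logging.getLogger(__name__)

PHASES = ("G1", "S1", "S2", "S3", "S4", "G2")
LATE_PHASES = ("S4", "G2")
CLASS_NAMES = ("early/mid S", "mid/late S", "late S/G2")


@dataclass
class RepliProfileSet:
    """Per-PMD concatenated phase profiles, one block per phase."""

    pmds: pd.DataFrame
    matrix: np.ndarray  # (n_pmds, n_phases * n_cols)
    n_cols: int
    phases: tuple[str, ...] = PHASES

    def phase_block(self, phase: str) -> np.ndarray:
        i = self.phases.index(phase)
        return self.matrix[:, i * self.n_cols : (i + 1) * self.n_cols]


@dataclass
class ClassifierReport:
    """Held-out evaluation of the replication-class predictor."""

    confusion: np.ndarray  # (3, 3), rows = truth
    class_names: tuple[str, ...]
    per_class_accuracy: dict[str, float]
    average_accuracy: float
    best_params: dict
    cv_folds: int = 10
    cv_repeats: int = 5
    test_fraction: float = 0.25
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_names": list(self.class_names),
            "per_class_accuracy": self.per_class_accuracy,
            "average_accuracy": self.average_accuracy,
            "best_params": {k: str(v) for k, v in self.best_params.items()},
            "cv": {"folds": self.cv_folds, "repeats": self.cv_repeats,
                   "test_fraction": self.test_fraction},
            "seed": self.seed,
        }


def _impute_region_mean(values: np.ndarray) -> np.ndarray:
    """Replace NaN cells (e.g. flanks beyond chromosome ends) with row means."""
    out = values.copy()
    row_mean = np.nanmean(out, axis=1, keepdims=True)
    nan_rows = np.isnan(row_mean[:, 0])
    if nan_rows.any():
        row_mean[nan_rows, 0] = np.nanmean(out)
    mask = np.isnan(out)
    if mask.any():
        logger.info("imputed %d missing profile cells with region means", int(mask.sum()))
    out[mask] = np.broadcast_to(row_mean, out.shape)[mask]
    return out


def build_repli_profiles(
    pmds: SegmentSet,
    phase_tracks: dict[str, SignalTrack],
    body_len: int = 500_000,
    flank_len: int = 250_000,
    bin_size: int = 1_000,
) -> RepliProfileSet:
    missing = [p for p in PHASES if p not in phase_tracks]
    if missing:
        raise ValueError(f"missing phase tracks: {missing}")
    blocks = []
    for phase in PHASES:
        rsm = scale_regions_matrix(phase_tracks[phase], pmds, body_len, flank_len, bin_size)
        blocks.append(_impute_region_mean(rsm.values))
    matrix = np.concatenate(blocks, axis=1)
    return RepliProfileSet(pmds.df.reset_index(drop=True), matrix, blocks[0].shape[1])


def cluster_replication_timing(
    pmds: SegmentSet,
    phase_tracks: dict[str, SignalTrack],
    seed: int = 0,
    body_len: int = 500_000,
    flank_len: int = 250_000,
    bin_size: int = 1_000,
) -> tuple[np.ndarray, RepliProfileSet]:
    """k-means (k=3) over concatenated phase profiles.

    Returns (class names per PMD, profile set).  Clusters are named by
    ranking their mean late-phase (S4 + G2) signal: lowest = "early/mid S",
    highest = "late S/G2".
    """
    if len(pmds) < 3:
        raise ValueError("need at least 3 PMDs to form three replication classes")
    prof = build_repli_profiles(pmds, phase_tracks, body_len, flank_len, bin_size)
    km = KMeans(n_clusters=3, n_init=10, random_state=seed)
    raw = km.fit_predict(prof.matrix)
    sizes = np.bincount(raw, minlength=3)
    if (sizes < 2).any():
        logger.warning("cluster_replication_timing: near-empty cluster sizes %s", sizes)
    late = np.stack([prof.phase_block(p).mean(axis=1) for p in LATE_PHASES]).sum(axis=0)
    late_by_cluster = np.array([late[raw == c].mean() if (raw == c).any() else np.inf
                                for c in range(3)])
    order = np.argsort(late_by_cluster, kind="stable")
    name_of = {int(c): CLASS_NAMES[rank] for rank, c in enumerate(order)}
    labels = np.array([name_of[int(c)] for c in raw], dtype=object)
    return labels, prof


def build_histone_features(
    pmds: SegmentSet,
    histone_tracks: dict[str, SignalTrack],
    body_len: int = 500_000,
    flank_len: int = 250_000,
    bin_size: int = 1_000,
) -> np.ndarray:
    """Per-PMD feature vector: concatenated binned mark signals (NaN imputed
    with the region mean)."""
    blocks = []
    for mark in sorted(histone_tracks):
        rsm = scale_regions_matrix(histone_tracks[mark], pmds, body_len, flank_len, bin_size)
        blocks.append(_impute_region_mean(rsm.values))
    return np.concatenate(blocks, axis=1)


def one_vs_all_accuracies(confusion: np.ndarray, class_names) -> dict[str, float]:
    """Per-class (TP+TN)/N from a multiclass confusion matrix."""
    n = confusion.sum()
    out = {}
    for i, name in enumerate(class_names):
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = n - tp - fn - fp
        out[str(name)] = float((tp + tn) / n)
    return out


def train_replication_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    cv_folds: int = 10,
    cv_repeats: int = 5,
    test_fraction: float = 0.25,
) -> ClassifierReport:
    """Random-forest one-vs-all evaluation of the replication classes.

    The data are split 75/25 (stratified); the forest is selected by
    repeated stratified CV on the training part over a small grid
    (trees in {200, 500}, features per split in {sqrt(p), 0.2 p}) and then
    scored once on the held-out quarter.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    X_tr, X_te, y_tr, y_te = train_test_split(
        features, labels, test_size=test_fraction, stratify=labels, random_state=seed
    )
    if len(np.unique(y_tr)) < len(classes):
        raise ValueError("a class is absent from the training split")
    cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)
    grid = {"n_estimators": [200, 500], "max_features": ["sqrt", 0.2]}
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed), grid, cv=cv, scoring="accuracy", n_jobs=1
    )
    search.fit(X_tr, y_tr)
    pred = search.best_estimator_.predict(X_te)
    conf = confusion_matrix(y_te, pred, labels=classes)
    per_class = one_vs_all_accuracies(conf, classes)
    return ClassifierReport(
        confusion=conf,
        class_names=tuple(str(c) for c in classes),
        per_class_accuracy=per_class,
        average_accuracy=float(np.mean(list(per_class.values()))),
        best_params=search.best_params_,
        cv_folds=cv_folds,
        cv_repeats=cv_repeats,
        test_fraction=test_fraction,
        seed=seed,
    )
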