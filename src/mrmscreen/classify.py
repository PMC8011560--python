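"""Peak classification into target-congener classes, and evaluation metrics.

Every fitted peak is described by four features: its signed retention-time
difference to each of three designated injected standards, plus the MRM
channel it was found in.  A multiclass model (random forest, RBF support
vector machine, or Gaussian naive Bayes) maps these features onto known
congener class ids, so that target and non-target peaks alike are associated
with a known class.

Evaluation follows the usual confusion-count arithmetic: accuracy, precision,
recall and F1 over present/absent calls per (sample, class) pair, compared
against a manual reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.svm import SVC

from .peakfit import FittedPeak

Algorithm = Literal["random_forest", "svm", "naive_bayes"]
ALGORITHMS: tuple[str, ...] = ("random_forest", "svm", "naive_bayes")


@dataclass(frozen=True)
class PeakFeatureVector:
    """The four classification features of one peak."""

    drt1: float
    drt2: float
    drt3: float
    channel_id: int

    def as_array(self) -> np.ndarray:
        return np.array([self.drt1, self.drt2, self.drt3, self.channel_id], dtype=float)


@dataclass(frozen=True)
class LabeledPeak:
    """A feature vector with its congener-class label and source peak."""

    features: PeakFeatureVector
    label: int
    source_peak: FittedPeak | None = None

    @property
    def sample_id(self) -> str:
        return self.source_peak.sample_id if self.source_peak is not None else ""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass
class ClassifierModel:
    """A fitted multiclass model plus its cross-validated accuracy."""

    estimator: object
    algorithm: str
    cv_accuracy: float
    cv_folds: int


def extract_features(peak: FittedPeak, standard_rts: Sequence[float]) -> PeakFeatureVector:
    """Signed rt differences from a peak to the three designated standards."""
    if len(standard_rts) != 3:
        raise ValueError("exactly three designated standard retention times required")
    return PeakFeatureVector(
        drt1=peak.rt - float(standard_rts[0]),
        drt2=peak.rt - float(standard_rts[1]),
        drt3=peak.rt - float(standard_rts[2]),
        channel_id=peak.channel_id,
    )


def features_matrix(features: Sequence[PeakFeatureVector]) -> np.ndarray:
    if not features:
        return np.empty((0, 4))
    return np.vstack([f.as_array() for f in features])


def split_train_test(
    peaks: Sequence[LabeledPeak],
    train_fraction: float = 0.8,
    holdout_samples: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[list[LabeledPeak], list[LabeledPeak]]:
    """Split labelled peaks by sample, never splitting one sample's peaks.

    With ``holdout_samples`` given, those samples' peaks form the test set
    (location-holdout evaluation); otherwise whole samples are assigned to
    the test partition at random until roughly ``1 - train_fraction`` of the
    peaks are held out.
    """
    if not peaks:
        raise ValueError("no peaks to split")
    by_sample: dict[str, list[LabeledPeak]] = {}
    for p in peaks:
        by_sample.setdefault(p.sample_id, []).append(p)

    if holdout_samples is not None:
        holdout = set(holdout_samples)
        train = [p for p in peaks if p.sample_id not in holdout]
        test = [p for p in peaks if p.sample_id in holdout]
    else:
        rng = np.random.default_rng(seed)
        sample_ids = sorted(by_sample)
        rng.shuffle(sample_ids)
        n_total = len(peaks)
        test_ids: set[str] = set()
        n_test = 0
        for sid in sample_ids:
            if n_test >= (1.0 - train_fraction) * n_total:
                break
            test_ids.add(sid)
            n_test += len(by_sample[sid])
        train = [p for p in peaks if p.sample_id not in test_ids]
        test = [p for p in peaks if p.sample_id in test_ids]
    if not train or not test:
        raise ValueError("split produced an empty train or test partition")
    return train, test


def _make_estimator(algo: str, seed: int):
    # channel id (column 3) is nominal: one-hot for the kernel/Gaussian
    # models, raw integer for trees which split on it natively.
    categorical = ColumnTransformer(
        [
            ("drt", StandardScaler(), [0, 1, 2]),
            ("channel", OneHotEncoder(handle_unknown="ignore", sparse_output=False), [3]),
        ]
    )
    if algo == "random_forest":
        return RandomForestClassifier(
            n_estimators=100, max_features="sqrt", random_state=seed
        )
    if algo == "svm":
        return Pipeline(
            [("features", categorical), ("svc", SVC(kernel="rbf", C=10.0))]
        )
    if algo == "naive_bayes":
        # raw drt (per-class variances make scaling redundant) + one-hot
        # channel; var_smoothing keeps rare (class, channel) cells from
        # collapsing to zero variance and vetoing the class.
        nb_features = ColumnTransformer(
            [
                ("drt", "passthrough", [0, 1, 2]),
                ("channel", OneHotEncoder(handle_unknown="ignore", sparse_output=False), [3]),
            ]
        )
        return Pipeline(
            [("features", nb_features), ("nb", GaussianNB(var_smoothing=1e-2))]
        )
    raise ValueError(f"unknown algorithm {algo!r}; pick one of {ALGORITHMS}")


def train_classifier(
    train: Sequence[LabeledPeak],
    algo: Algorithm = "random_forest",
    cv_folds: int = 7,
    seed: int = 0,
) -> ClassifierModel:
    """Fit a seeded multiclass model and report its k-fold CV accuracy.

    Folds are stratified by class when every class has at least ``cv_folds``
    members, otherwise plain shuffled folds are used.
    """
    if len(train) < 2 * cv_folds:
        raise ValueError(f"need at least {2 * cv_folds} training peaks")
    X = features_matrix([p.features for p in train])
    y = np.array([p.label for p in train])
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    est = _make_estimator(algo, seed)
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() >= cv_folds:
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    else:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(est, X, y, cv=cv, scoring="accuracy")
    est.fit(X, y)
    return ClassifierModel(
        estimator=est,
        algorithm=algo,
        cv_accuracy=float(scores.mean()),
        cv_folds=cv_folds,
    )


def predict_classes(
    model: ClassifierModel, features: Sequence[PeakFeatureVector]
) -> list[int]:
    """Predict one congener class id per feature vector."""
    if not features:
        return []
    X = features_matrix(features)
    return [int(c) for c in model.estimator.predict(X)]


def training_accuracy(model: ClassifierModel, train: Sequence[LabeledPeak]) -> float:
    pred = predict_classes(model, [p.features for p in train])
    truth = [p.label for p in train]
    return float(np.mean([a == b for a, b in zip(pred, truth)]))


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(c: ConfusionCounts, zero_division: str = "raise") -> Metrics:
    """Accuracy, precision, recall and F1 from confusion counts.

    Undefined metrics (zero denominator) raise by default; with
    ``zero_division="zero"`` they are reported as 0 instead.
    """
    import logging

    if c.total == 0:
        raise ValueError("metrics undefined for all-zero confusion counts")
    accuracy = (c.tp + c.tn) / c.total

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            if zero_division == "zero":
                logging.getLogger(__name__).warning("%s undefined; reporting 0", name)
                return 0.0
            raise ValueError(f"{name} undefined: zero denominator")
        return num / den

    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    return Metrics(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1_from_precision_recall(precision, recall),
    )


def label_against_manual(
    auto: Iterable[tuple[str, int]],
    manual: Iterable[tuple[str, int]],
    universe: Iterable[tuple[str, int]],
) -> ConfusionCounts:
    """Confusion counts of autonomous vs manual present/absent calls.

    ``auto`` and ``manual`` are sets of (sample_id, class_id) pairs in which a
    congener was detected; ``universe`` enumerates every pair under
    consideration.  TP = found by both; TN = found by neither; FP = found
    only autonomously; FN = found only manually.
    """
    auto_s, manual_s, universe_s = set(auto), set(manual), set(universe)
    if not auto_s <= universe_s or not manual_s <= universe_s:
        raise ValueError("auto and manual detections must lie within the universe")
    tp = len(auto_s & manual_s)
    fp = len(auto_s - manual_s)
    fn = len(manual_s - auto_s)
    tn = len(universe_s - (auto_s | manual_s))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
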