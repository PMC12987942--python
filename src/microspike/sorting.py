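"""Supervised assignment of detected spikes to fiber tracks.

Background-evoked spikes carry reliable fiber labels (the marking method),
so sorting is cast as supervised classification: three classifier kinds
(one-class SVM trained on the track of interest only; a multi-class RBF
SVM; gradient-boosted trees) times three feature sets are tuned by seeded
random search with 5-fold stratified cross-validation, maximizing the mean
one-vs-rest F1 of the track of interest.  The best combination is retrained
on all background spikes and applied to the detected spikes.

Margin classifiers receive standardized features (scaler fit on training
folds only); trees consume raw features.  With a fixed seed the whole
cv → train → assign chain is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, OneClassSVM
from xgboost import XGBClassifier

from ._errors import InsufficientDataError, ValidationError
from .features import FEATURE_SETS, featurize
from .waveforms import SpikeWaveform

__all__ = [
    "CLASSIFIERS",
    "SEARCH_SPACES",
    "SorterSpec",
    "CVResult",
    "SortingResult",
    "TrainedSorter",
    "ModelSelection",
    "cv_optimize",
    "train_final",
    "assign",
    "select_model",
]

logger = logging.getLogger(__name__)

CLASSIFIERS = ("one_class_svm", "svm", "xgboost")

#: Frozen hyperparameter search spaces.  "log" entries are sampled
#: log-uniformly, "int" uniformly over integers, "float" uniformly.
SEARCH_SPACES: dict[str, dict[str, tuple]] = {
    "svm": {"C": ("log", 1e-2, 1e3), "gamma": ("log", 1e-4, 1e1)},
    "one_class_svm": {"nu": ("float", 0.01, 0.5), "gamma": ("log", 1e-4, 1e1)},
    "xgboost": {
        "max_depth": ("int", 2, 8),
        "learning_rate": ("log", 0.01, 0.3),
        "n_estimators": ("int", 50, 500),
    },
}

# Tie-break preference when CV scores are exactly equal.
FEATURE_PREFERENCE = ("w_raw", "spdf", "spdf_fv3")
CLASSIFIER_PREFERENCE = ("xgboost", "svm", "one_class_svm")

MIN_ONE_CLASS_SPIKES = 10


@dataclass
class SorterSpec:
    """A classifier/feature-set choice with concrete hyperparameters."""

    classifier: str
    feature_set: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValidationError(f"unknown classifier {self.classifier!r}")
        if self.feature_set not in FEATURE_SETS:
            raise ValidationError(f"unknown feature set {self.feature_set!r}")


@dataclass
class CVResult:
    fold_f1: list[float]
    mean_f1: float
    best_params: dict
    n_trials: int


@dataclass
class SortingResult:
    """Per-spike track assignment; one-class outliers are ``"rejected"``."""

    labels: np.ndarray
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)


def _sample_params(classifier: str, rng: np.random.Generator) -> dict:
    params = {}
    for name, (kind, lo, hi) in SEARCH_SPACES[classifier].items():
        if kind == "log":
            params[name] = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
        elif kind == "int":
            params[name] = int(rng.integers(lo, hi + 1))
        else:
            params[name] = float(rng.uniform(lo, hi))
    return params


def _build_estimator(classifier: str, params: dict, seed: int):
    if classifier == "svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", SVC(kernel="rbf", C=params["C"], gamma=params["gamma"])),
            ]
        )
    if classifier == "one_class_svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", OneClassSVM(kernel="rbf", nu=params["nu"], gamma=params["gamma"])),
            ]
        )
    # exact splits: with tens-to-hundreds of training spikes the histogram
    # approximation is unnecessary and can place splits inside the margin
    return XGBClassifier(
        max_depth=params["max_depth"],
        learning_rate=params["learning_rate"],
        n_estimators=params["n_estimators"],
        n_jobs=1,
        tree_method="exact",
        random_state=seed,
        verbosity=0,
        eval_metric="logloss",
    )


def _encode(y: np.ndarray) -> tuple[np.ndarray, list]:
    classes = sorted(set(y))
    mapping = {c: i for i, c in enumerate(classes)}
    return np.array([mapping[v] for v in y]), classes


def _fold_f1(
    classifier: str,
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    interest: str,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    seed: int,
    objective: str,
) -> float:
    est = _build_estimator(classifier, params, seed)
    y_val = y[val_idx]
    if classifier == "one_class_svm":
        members = train_idx[y[train_idx] == interest]
        est.fit(X[members])
        pred_in = est.predict(X[val_idx]) == 1
        return float(f1_score(y_val == interest, pred_in, zero_division=0))
    if classifier == "xgboost":
        y_enc, classes = _encode(y)
        est.fit(X[train_idx], y_enc[train_idx])
        pred = np.array([classes[i] for i in est.predict(X[val_idx])], dtype=object)
    else:
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[val_idx])
    if objective == "macro":
        return float(f1_score(y_val, pred, average="macro", zero_division=0))
    return float(f1_score(y_val == interest, pred == interest, zero_division=0))


def _validate_training(y: np.ndarray, interest: str, classifier: str, n_folds: int) -> None:
    labels, counts = np.unique(y, return_counts=True)
    if interest not in labels:
        raise ValidationError(f"interest label {interest!r} not present in training data")
    if classifier == "one_class_svm":
        if counts[list(labels).index(interest)] < MIN_ONE_CLASS_SPIKES:
            raise InsufficientDataError(
                f"one-class SVM needs >= {MIN_ONE_CLASS_SPIKES} spikes of {interest!r}"
            )
    elif len(labels) < 2:
        raise ValidationError("multi-class sorter needs >= 2 labeled tracks")
    if counts.min() < n_folds:
        raise InsufficientDataError(
            f"stratified {n_folds}-fold CV needs >= {n_folds} spikes per track"
        )


def cv_optimize(
    X: np.ndarray,
    y: Sequence[str],
    interest_label: str,
    spec_template: SorterSpec,
    n_trials: int = 50,
    n_folds: int = 5,
    objective: str = "interest",
) -> CVResult:
    """Randomized hyperparameter search under stratified cross-validation.

    ``n_trials`` parameter sets are drawn (seeded) from the frozen search
    space of the classifier; each is scored by the mean F1 across
    ``n_folds`` stratified folds (one-vs-rest for ``interest_label`` by
    default, macro-averaged with ``objective="macro"``).  Folds are shared
    across trials so scores are comparable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    _validate_training(y, interest_label, spec_template.classifier, n_folds)
    rng = np.random.default_rng(spec_template.seed)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec_template.seed)
    folds = list(skf.split(X, y.astype(str)))
    best: tuple[float, dict, list[float]] | None = None
    for _ in range(n_trials):
        params = _sample_params(spec_template.classifier, rng)
        scores = [
            _fold_f1(
                spec_template.classifier,
                params,
                X,
                y,
                interest_label,
                tr,
                va,
                spec_template.seed,
                objective,
            )
            for tr, va in folds
        ]
        mean = float(np.mean(scores))
        if best is None or mean > best[0]:
            best = (mean, params, scores)
    assert best is not None
    return CVResult(
        fold_f1=[float(s) for s in best[2]],
        mean_f1=best[0],
        best_params=best[1],
        n_trials=n_trials,
    )


@dataclass
class TrainedSorter:
    """A sorter fitted on all background spikes, ready for assignment."""

    spec: SorterSpec
    interest_label: str
    model: object
    classes: list | None  # None for one-class

    def save(self, path) -> None:
        """Persist the fitted model (pickle) with a JSON spec sidecar."""
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        sidecar = {
            "classifier": self.spec.classifier,
            "feature_set": self.spec.feature_set,
            "hyperparams": self.spec.hyperparams,
            "seed": self.spec.seed,
            "interest_label": self.interest_label,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "TrainedSorter":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise ValidationError("file does not contain a TrainedSorter")
        return obj


def train_final(
    X: np.ndarray,
    y: Sequence[str],
    interest_label: str,
    spec: SorterSpec,
) -> TrainedSorter:
    """Retrain on *all* background spikes with the chosen hyperparameters.

    The one-class SVM is fitted on the interest track's spikes only; the
    multi-class sorters on every labeled track.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if not spec.hyperparams:
        raise ValidationError("spec.hyperparams must be chosen (run cv_optimize)")
    est = _build_estimator(spec.classifier, spec.hyperparams, spec.seed)
    if spec.classifier == "one_class_svm":
        est.fit(X[y == interest_label])
        return TrainedSorter(spec, interest_label, est, None)
    if spec.classifier == "xgboost":
        y_enc, classes = _encode(y)
        est.fit(X, y_enc)
        return TrainedSorter(spec, interest_label, est, classes)
    est.fit(X, y)
    return TrainedSorter(spec, interest_label, est, sorted(set(y)))


def assign(sorter: TrainedSorter, X: np.ndarray) -> SortingResult:
    """Assign each detected spike a track label (or ``"rejected"``)."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return SortingResult(labels=np.array([], dtype=object), scores=np.array([]))
    fitted = getattr(sorter.model, "n_features_in_", None)
    if fitted is not None and X.shape[1] != fitted:
        raise ValidationError(
            f"feature dimension {X.shape[1]} does not match the sorter's {fitted}"
        )
    if sorter.spec.classifier == "one_class_svm":
        raw = sorter.model.predict(X)
        labels = np.where(raw == 1, sorter.interest_label, "rejected").astype(object)
        scores = sorter.model.decision_function(X)
        return SortingResult(labels=labels, scores=np.asarray(scores, dtype=float))
    if sorter.spec.classifier == "xgboost":
        proba = sorter.model.predict_proba(X)
        idx = proba.argmax(axis=1)
        labels = np.array([sorter.classes[i] for i in idx], dtype=object)
        scores = proba.max(axis=1)
        return SortingResult(labels=labels, scores=np.asarray(scores, dtype=float))
    labels = sorter.model.predict(X).astype(object)
    df = sorter.model.decision_function(X)
    scores = np.abs(np.asarray(df, dtype=float)).reshape(len(labels), -1).max(axis=1)
    return SortingResult(labels=labels, scores=scores)


@dataclass
class ModelSelection:
    best_spec: SorterSpec
    best_cv: CVResult
    grid: pd.DataFrame


def select_model(
    waveforms: Sequence[SpikeWaveform],
    labels: Sequence[str],
    interest_label: str,
    seed: int = 0,
    n_trials: int = 50,
    objective: str = "interest",
) -> ModelSelection:
    """Evaluate all 9 feature-set x classifier combinations and pick the best.

    Returns the argmax-mean-F1 specification together with the full grid for
    reporting.  Exact ties are broken by the fixed preference order
    w_raw > spdf > spdf_fv3 and xgboost > svm > one_class_svm, and logged.
    """
    y = np.asarray(labels, dtype=object)
    rows = []
    results: dict[tuple[str, str], CVResult] = {}
    for fs in FEATURE_PREFERENCE:
        X = featurize(waveforms, fs)
        for clf in CLASSIFIER_PREFERENCE:
            spec = SorterSpec(classifier=clf, feature_set=fs, seed=seed)
            cv = cv_optimize(X, y, interest_label, spec, n_trials=n_trials, objective=objective)
            results[(fs, clf)] = cv
            rows.append(
                {
                    "feature_set": fs,
                    "classifier": clf,
                    "mean_f1": cv.mean_f1,
                    "best_params": cv.best_params,
                }
            )
    grid = pd.DataFrame(rows)
    best_f1 = grid["mean_f1"].max()
    # rows were generated in preference order, so the first maximum wins ties
    tied = grid[grid["mean_f1"] == best_f1]
    if len(tied) > 1:
        logger.info(
            "model selection tie at F1=%.4f among %s; preference order applied",
            best_f1,
            [(r.feature_set, r.classifier) for r in tied.itertuples()],
        )
    top = tied.iloc[0]
    cv = results[(top.feature_set, top.classifier)]
    best_spec = SorterSpec(
        classifier=top.classifier,
        feature_set=top.feature_set,
        hyperparams=dict(cv.best_params),
        seed=seed,
    )
    return ModelSelection(best_spec=best_spec, best_cv=cv, grid=grid)
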