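"""SVM species identification with per-object confidence.

A radial-basis-function support vector machine on standardized shape
features assigns each tracked object a species label and a confidence,
taken as the maximum posterior class probability from pairwise-coupling
(Platt) calibration.  Two cross-validation protocols are provided: the
standard k-fold (train on k-1 folds, test on 1) and the inverted
protocol in which each 1/k subset serves as the *training* set and the
remaining (k-1)/k of the library is scored — the protocol used when a
reference library is small and hand-curated.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainParams:
    kernel: str = "rbf"
    C: float = 10.0
    gamma: str | float = "scale"
    probability: bool = True
    seed: int = 0


@dataclass
class LabeledExample:
    features: np.ndarray
    label: str
    source_id: str


@dataclass
class LabeledLibrary:
    examples: list[LabeledExample] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.examples)

    def __post_init__(self) -> None:
        ids = [e.source_id for e in self.examples]
        if len(set(ids)) != len(ids):
            raise ValueError("source image ids must be unique")

    @property
    def X(self) -> np.ndarray:
        return np.array([e.features for e in self.examples], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array([e.label for e in self.examples])

    @property
    def labels(self) -> list[str]:
        return sorted(set(e.label for e in self.examples))


@dataclass
class Identification:
    track_id: int
    species: str
    confidence: float
    probabilities: dict[str, float] = field(default_factory=dict)
    override_confidence: float | None = None


@dataclass
class FittedModel:
    pipeline: Pipeline
    classes: list[str]
    n_features: int
    format_version: int = MODEL_FORMAT_VERSION


def train(library: LabeledLibrary,
          params: TrainParams = TrainParams()) -> FittedModel:
    """Fit the SVM on a labeled feature library.

    Feature standardization is fitted on the training data only and
    travels with the model.  Requires at least two classes with at
    least three examples each; non-finite feature rows are rejected
    with the offending source id.
    """
    X, y = library.X, library.y
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        offenders = [library.examples[i].source_id for i in np.nonzero(bad)[0]]
        raise ValueError(f"non-finite features in examples: {offenders}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes to train, got {list(classes)}")
    if counts.min() < 3:
        small = classes[counts < 3]
        raise ValueError(f"need >= 3 examples per class; too few for {list(small)}")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel=params.kernel, C=params.C, gamma=params.gamma,
                    probability=params.probability,
                    random_state=params.seed)),
    ])
    pipe.fit(X, y)
    return FittedModel(pipeline=pipe, classes=list(pipe.classes_),
                       n_features=X.shape[1])


def predict(model: FittedModel, features: np.ndarray,
            track_id: int = -1) -> Identification:
    """Identify one object; confidence is the max class probability."""
    features = np.asarray(features, dtype=float).ravel()
    if features.size != model.n_features:
        raise ValueError(
            f"feature length {features.size} != model expectation {model.n_features}"
        )
    proba = model.pipeline.predict_proba(features[None, :])[0]
    best = int(np.argmax(proba))
    return Identification(
        track_id=track_id,
        species=model.classes[best],
        confidence=float(proba[best]),
        probabilities={c: float(p) for c, p in zip(model.classes, proba)},
    )


def predict_batch(model: FittedModel, X: np.ndarray,
                  track_ids: list[int] | None = None) -> list[Identification]:
    X = np.asarray(X, dtype=float)
    if track_ids is None:
        track_ids = list(range(len(X)))
    proba = model.pipeline.predict_proba(X)
    out = []
    for tid, p in zip(track_ids, proba):
        best = int(np.argmax(p))
        out.append(Identification(
            track_id=tid, species=model.classes[best],
            confidence=float(p[best]),
            probabilities={c: float(v) for c, v in zip(model.classes, p)},
        ))
    return out


@dataclass
class KFoldResult:
    per_fold: list[float]
    average: float
    skipped_folds: list[int]


def kfold_paper_protocol(library: LabeledLibrary, k: int = 10,
                         seed: int = 0,
                         params: TrainParams | None = None) -> KFoldResult:
    """Inverted k-fold: train on each 1/k subset, test on the other 90%.

    Subsets are stratified by label where possible and seeded.  A fold
    whose training subset lacks two classes (or three examples of some
    class) is skipped with a warning and reported in the result.
    """
    return _kfold(library, k, seed, params, invert=True)


def kfold_standard(library: LabeledLibrary, k: int = 10, seed: int = 0,
                   params: TrainParams | None = None) -> KFoldResult:
    """Conventional k-fold: train on k-1 folds, test on the held-out one."""
    return _kfold(library, k, seed, params, invert=False)


def _kfold(library: LabeledLibrary, k: int, seed: int,
           params: TrainParams | None, invert: bool) -> KFoldResult:
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(library) < k:
        raise ValueError(f"library size {len(library)} < k = {k}")
    if k >= len(library):
        raise ValueError(
            f"k = {k} leaves single-example folds that cannot contain two classes"
        )
    if params is None:
        params = TrainParams(seed=seed)
    X, y = library.X, library.y
    counts = np.unique(y, return_counts=True)[1]
    n_splits = min(k, int(counts.min())) if invert else k
    if n_splits < k:
        # stratification impossible at k; fall back to unstratified folds
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(library))
        fold_sets = np.array_split(order, k)
        splits = [(np.setdiff1d(order, f), f) for f in fold_sets]
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))

    per_fold, skipped = [], []
    for fold_no, (big, small) in enumerate(splits):
        train_idx, test_idx = (small, big) if invert else (big, small)
        sub = LabeledLibrary([library.examples[i] for i in train_idx])
        try:
            model = train(sub, params)
        except ValueError as exc:
            warnings.warn(f"fold {fold_no} skipped: {exc}", stacklevel=2)
            skipped.append(fold_no)
            continue
        pred = model.pipeline.predict(X[test_idx])
        per_fold.append(float(np.mean(pred == y[test_idx])))
    if not per_fold:
        raise ValueError("every fold was skipped; library too small or unbalanced")
    return KFoldResult(per_fold=per_fold,
                       average=float(np.mean(per_fold)),
                       skipped_folds=skipped)


@dataclass
class HoldoutReport:
    per_species: dict[str, float]
    overall: float
    n_test: int


def holdout_evaluate(model: FittedModel, test: LabeledLibrary) -> HoldoutReport:
    """Per-species recall and overall accuracy on a labeled test set."""
    X, y = test.X, test.y
    pred = model.pipeline.predict(X)
    per = {}
    for species in sorted(set(y)):
        sel = y == species
        per[species] = float(np.mean(pred[sel] == species))
    return HoldoutReport(per_species=per,
                         overall=float(np.mean(pred == y)),
                         n_test=len(test))


# -- synthetic training data ------------------------------------------------

def build_silhouette_library(species_specs: dict, templates: list,
                             n_per_species: int = 100, seed: int = 0,
                             orientation_jitter_deg: float = 12.0,
                             scale_range: tuple[float, float] = (0.85, 1.25)):
    """Render a labeled feature library from species shape specs.

    Each example is a silhouette rendered at a jittered orientation and
    scale, featurized against ``templates``.  This emulates the curated
    image library used to train the identifier in the field system.
    """
    from . import features as ft
    from . import synthetic_video as sv

    rng = np.random.default_rng(seed)
    order = [t.species for t in templates]
    examples = []
    for name, spec in species_specs.items():
        for j in range(n_per_species):
            deg = rng.uniform(-orientation_jitter_deg, orientation_jitter_deg)
            sc = rng.uniform(*scale_range)
            mask = sv.species_silhouette(spec, deg, sc)
            fv = ft.feature_vector(mask.astype(float), mask, templates)
            examples.append(LabeledExample(
                features=fv.to_array(order), label=name,
                source_id=f"{name}_{j:04d}",
            ))
    return LabeledLibrary(examples)


def identify_tracks(model: FittedModel, tracks, templates) -> list[Identification]:
    """Classify each track from its best (largest-area) detection mask."""
    from . import features as ft

    order = [t.species for t in templates]
    out = []
    for track in tracks:
        det = track.best_detection()
        fv = ft.feature_vector(det.mask.astype(float), det.mask, templates)
        out.append(predict(model, fv.to_array(order), track.track_id))
    return out


# -- persistence ------------------------------------------------------------

def save_model(model: FittedModel, path: str | Path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"format_version": model.format_version, "model": model}, fh)


def load_model(path: str | Path) -> FittedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format {payload['format_version']} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return payload["model"]


def write_identifications(path: str | Path, idents: list[Identification]) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["track_id", "species", "confidence", "override_confidence"])
        for ident in idents:
            writer.writerow([
                ident.track_id, ident.species, f"{ident.confidence:.6f}",
                "" if ident.override_confidence is None
                else f"{ident.override_confidence:.6f}",
            ])
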