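"""Per-length classifier grid: training, persistence, prediction.

One classifier is trained for every (binding-site length, negative scheme)
cell — up to 9 lengths x 2 schemes = 18 models.  Within a cell the default
pipeline is: estimate per-DBD-type base-preference profiles from the positive
*training* records only, encode all records (profiles + binding-mode DBD
features), and fit a 100-tree random forest.  Gaussian naive Bayes and
k-nearest-neighbour (odd k selected from 3..103 by 10-fold cross-validated
F1) are available as alternative classifiers.

All randomness is seeded; refitting with the same seed reproduces the same
model, probabilities and metrics.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier

from .constants import DEFAULT_THRESHOLD, TFBS_LENGTHS
from .errors import (
    ConfigurationError, KeyMismatchError, NoDataError, StratificationError, TrainingError,
)
from .evaluation import MetricsReport, evaluate
from .feature_encoding import BASE_PREFERENCE, encode_records
from .motif_tools import BasePreferenceProfile, compute_base_preference
from .negative_sampling import generate_negatives

DEFAULT_KNN_GRID = tuple(range(3, 104, 2))
DEFAULT_RF_TREES = 100

_CLASSIFIERS = ("RF", "NB", "KNN")


@dataclass(frozen=True)
class PredictionResult:
    """Positive-class probability for one (TF, site) pair under one model."""

    tf_id: str
    tfbs_sequence: str
    length: int
    prob: float
    scheme: str

    def label_at(self, threshold: float) -> bool:
        return self.prob >= threshold


@dataclass
class LengthModel:
    """A fitted classifier for one (length, negative-scheme) cell."""

    length: int
    scheme: str
    classifier: str
    hyperparams: dict
    encoding_mode: str
    include_dbd: bool
    profiles: dict[str, BasePreferenceProfile]
    estimator: object = None
    training_seed: int = 0
    fitted: bool = False

    def _check(self, rec) -> None:
        if rec.length != self.length:
            raise KeyMismatchError(
                f"record length {rec.length} does not match model length {self.length}"
            )
        if self.encoding_mode == BASE_PREFERENCE and rec.dbd_type not in self.profiles:
            raise KeyMismatchError(
                f"DBD type {rec.dbd_type!r} unknown to the ({self.length}, {self.scheme}) model"
            )


def split_train_test(records, ratio: float = 0.70, seed: int = 0):
    """Stratified 70:30-style split, by label within each length group.

    Each (length, label) stratum contributes round(ratio * n) records to the
    training partition.  Partitions are disjoint, exhaustive and reproducible
    for a fixed seed.
    """
    records = list(records)
    if not 0 < ratio < 1:
        raise ConfigurationError(f"split ratio must lie strictly in (0, 1), got {ratio}")
    strata = defaultdict(list)
    for i, rec in enumerate(records):
        strata[(rec.length, rec.label)].append(i)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for key in sorted(strata):
        idx = np.array(strata[key])
        if len(idx) < 2:
            raise StratificationError(f"stratum (length, label)={key} has {len(idx)} record(s)")
        perm = rng.permutation(len(idx))
        n_train = int(round(ratio * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both partitions non-empty
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    train = [records[i] for i in sorted(train_idx)]
    test = [records[i] for i in sorted(test_idx)]
    return train, test


def select_knn_k(X, y, k_grid=DEFAULT_KNN_GRID, folds: int = 10, seed: int = 0):
    """Pick the neighbour count maximising mean cross-validated F1.

    Returns ``(best_k, table)`` where table lists (k, mean F1).  Ties break
    toward the smaller k.  Raises :class:`TrainingError` when the folds cannot
    all contain both classes.
    """
    y = np.asarray(y)
    counts = np.bincount(y)
    if len(counts) < 2 or counts.min() < folds:
        raise TrainingError(
            f"each class needs at least {folds} records for {folds}-fold selection"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    table = []
    for k in k_grid:
        if k > len(y) - len(y) // folds:
            continue  # k larger than any training fold
        est = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
        scores = cross_val_score(est, X, y, cv=cv, scoring="f1")
        table.append((k, float(np.mean(scores))))
    if not table:
        raise TrainingError("no usable k in the grid for this training-set size")
    best_k = max(table, key=lambda t: (t[1], -t[0]))[0]
    return best_k, table


def _make_estimator(classifier: str, hyperparams: dict, seed: int):
    if classifier == "RF":
        return RandomForestClassifier(
            n_estimators=hyperparams.get("n_trees", DEFAULT_RF_TREES), random_state=seed
        )
    if classifier == "NB":
        return GaussianNB()
    if classifier == "KNN":
        return KNeighborsClassifier(n_neighbors=hyperparams["k"], metric="euclidean")
    raise ConfigurationError(f"unknown classifier {classifier!r} (expected one of {_CLASSIFIERS})")


def train_length_model(
    train, length: int, scheme: str, classifier: str = "RF",
    encoding_mode: str = BASE_PREFERENCE, include_dbd: bool = True,
    seed: int = 0, rf_trees: int = DEFAULT_RF_TREES, knn_grid=DEFAULT_KNN_GRID,
) -> LengthModel:
    """Fit one (length, scheme) model from labelled records of that length.

    Base-preference profiles are estimated from the positive training records
    only (one per DBD type present), then frozen into the model.
    """
    train = list(train)
    if any(rec.length != length for rec in train):
        raise KeyMismatchError(f"all training records must have length {length}")
    labels = {rec.label for rec in train}
    if labels != {0, 1}:
        raise TrainingError("training requires both positive and negative records")

    profiles: dict[str, BasePreferenceProfile] = {}
    if encoding_mode == BASE_PREFERENCE:
        by_type = defaultdict(list)
        for rec in train:
            if rec.label == 1:
                by_type[rec.dbd_type].append(rec)
        if not by_type:
            raise NoDataError("no positive records to estimate profiles from")
        profiles = {
            t: compute_base_preference(recs, t, length) for t, recs in sorted(by_type.items())
        }
        missing = {rec.dbd_type for rec in train} - set(profiles)
        if missing:
            raise KeyMismatchError(
                f"DBD type(s) {sorted(missing)} appear only in negatives; no profile available"
            )

    X, y = encode_records(train, profiles or None, encoding_mode, include_dbd)
    hyperparams = {}
    if classifier == "RF":
        hyperparams["n_trees"] = rf_trees
    elif classifier == "KNN":
        best_k, _ = select_knn_k(X, y, k_grid=knn_grid, seed=seed)
        hyperparams["k"] = best_k
    estimator = _make_estimator(classifier, hyperparams, seed)
    estimator.fit(X, y)
    return LengthModel(
        length=length, scheme=scheme, classifier=classifier, hyperparams=hyperparams,
        encoding_mode=encoding_mode, include_dbd=include_dbd, profiles=profiles,
        estimator=estimator, training_seed=seed, fitted=True,
    )


def predict_proba(model: LengthModel, pairs) -> list[PredictionResult]:
    """Positive-class probability for each pair under a fitted model.

    Every pair must match the model's length and, in base-preference mode,
    carry a DBD type the model has a profile for.
    """
    pairs = list(pairs)
    if not pairs:
        return []
    if not model.fitted:
        raise TrainingError("model is not fitted")
    for rec in pairs:
        model._check(rec)
    X, _ = encode_records(pairs, model.profiles or None, model.encoding_mode, model.include_dbd)
    probs = positive_proba(model.estimator, X)
    return [
        PredictionResult(
            tf_id=rec.tf_id, tfbs_sequence=rec.tfbs_sequence, length=rec.length,
            prob=float(p), scheme=model.scheme,
        )
        for rec, p in zip(pairs, probs)
    ]


def positive_proba(estimator, X: np.ndarray) -> np.ndarray:
    """Column of predict_proba corresponding to the positive class (label 1)."""
    proba = estimator.predict_proba(X)
    col = list(estimator.classes_).index(1)
    return proba[:, col]


@dataclass
class ModelRegistry:
    """The trained model grid plus per-model hold-out metrics."""

    models: dict[tuple[int, str], LengthModel] = field(default_factory=dict)
    metrics: dict[tuple[int, str], MetricsReport] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def get(self, length: int, scheme: str) -> LengthModel:
        key = (length, scheme.upper())
        if key not in self.models:
            raise ConfigurationError(f"registry has no model for (length={length}, {scheme})")
        return self.models[key]

    @property
    def lengths(self) -> list[int]:
        return sorted({length for length, _ in self.models})

    def dbd_types(self, length: int, scheme: str = "RP") -> set[str]:
        return set(self.get(length, scheme).profiles)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"models": [], **self.manifest}
        for (length, scheme), model in sorted(self.models.items()):
            stem = f"model_L{length}_{scheme}"
            joblib.dump(model.estimator, directory / f"{stem}.joblib")
            profiles_json = {
                t: {"length": p.length, "n": p.n, "matrix": p.matrix.tolist()}
                for t, p in model.profiles.items()
            }
            entry = {
                "length": length, "scheme": scheme, "classifier": model.classifier,
                "hyperparams": model.hyperparams, "encoding_mode": model.encoding_mode,
                "include_dbd": model.include_dbd, "training_seed": model.training_seed,
                "estimator_file": f"{stem}.joblib", "profiles": profiles_json,
            }
            if (length, scheme) in self.metrics:
                entry["holdout_metrics"] = {
                    k: (None if np.isnan(v) else v)
                    for k, v in self.metrics[(length, scheme)].as_dict().items()
                }
            manifest["models"].append(entry)
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "ModelRegistry":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        registry = cls(manifest={k: v for k, v in manifest.items() if k != "models"})
        for entry in manifest["models"]:
            profiles = {
                t: BasePreferenceProfile(
                    dbd_type=t, length=pj["length"], matrix=np.array(pj["matrix"]), n=pj["n"]
                )
                for t, pj in entry["profiles"].items()
            }
            model = LengthModel(
                length=entry["length"], scheme=entry["scheme"], classifier=entry["classifier"],
                hyperparams=entry["hyperparams"], encoding_mode=entry["encoding_mode"],
                include_dbd=entry["include_dbd"], profiles=profiles,
                estimator=joblib.load(directory / entry["estimator_file"]),
                training_seed=entry["training_seed"], fitted=True,
            )
            registry.models[(model.length, model.scheme)] = model
            hm = entry.get("holdout_metrics")
            if hm:
                registry.metrics[(model.length, model.scheme)] = MetricsReport(
                    **{k: (np.nan if v is None else v) for k, v in hm.items()}
                )
        return registry


def train_suite(
    positives, schemes=("RP", "RW"), lengths=TFBS_LENGTHS, classifier: str = "RF",
    encoding_mode: str = BASE_PREFERENCE, include_dbd: bool = True,
    split_ratio: float = 0.70, negative_ratio: float = 1.0, seed: int = 0,
    rf_trees: int = DEFAULT_RF_TREES, threshold: float = DEFAULT_THRESHOLD,
) -> ModelRegistry:
    """Train the full per-length model grid from positive interaction records.

    For each scheme, negatives are generated once over all positives (per
    length group, before the train/test split), each length group is split
    stratified by label, a model is fitted on the training part and its
    hold-out metrics recorded.  Lengths with no positives are skipped.
    """
    positives = [p for p in positives if p.label == 1]
    if not positives:
        raise NoDataError("no positive interactions supplied")
    registry = ModelRegistry(manifest={
        "classifier": classifier, "encoding_mode": encoding_mode, "include_dbd": include_dbd,
        "split_ratio": split_ratio, "negative_ratio": negative_ratio, "seed": seed,
    })
    by_length = defaultdict(list)
    for p in positives:
        by_length[p.length].append(p)

    for scheme_idx, scheme in enumerate(sorted(s.upper() for s in schemes)):
        scheme_seed = (seed * 7919 + scheme_idx * 104729 + 1) % (2**31)
        negatives = generate_negatives(
            scheme, positives, ratio=negative_ratio, seed=scheme_seed
        )
        neg_by_length = defaultdict(list)
        for n in negatives.records:
            neg_by_length[n.length].append(n)
        registry.manifest.setdefault("excluded_tfbs", {})[scheme] = negatives.excluded_tfbs

        for length in lengths:
            if length not in by_length:
                continue
            records = by_length[length] + neg_by_length.get(length, [])
            model_seed = (scheme_seed + length * 9973) % (2**31)
            train, test = split_train_test(records, ratio=split_ratio, seed=model_seed)
            model = train_length_model(
                train, length, scheme, classifier=classifier, encoding_mode=encoding_mode,
                include_dbd=include_dbd, seed=model_seed, rf_trees=rf_trees,
            )
            registry.models[(length, scheme)] = model
            results = predict_proba(model, test)
            labelled = [(rec.label, r.prob) for rec, r in zip(test, results)]
            registry.metrics[(length, scheme)] = evaluate(labelled, threshold=threshold)
    if not registry.models:
        raise NoDataError("no (length, scheme) cell had data to train on")
    return registry
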