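"""Subject-group cross-validation, accuracy/confusion metrics, embedding export.

Evaluation is leave-one-group-out over subjects: the subject pool is
partitioned into near-equal groups (15 subjects -> 5 groups of 3 by
default) and each fold trains on all groups but one and tests on the
held-out group, so test subjects are entirely unseen.  Within the
training folds a temporal 75/25 split supplies validation data from the
same subjects at later moments.  Accuracy is window-level (each window
one vote); recording-level majority voting is available but off by
default.

The label-scheme comparison runs the identical fold plan, windows and
initial weights twice — once with one-hot targets, once with smoothed
targets — so the encoding is the only varying factor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .dataset import Dataset, Gesture, N_CLASSES
from .model import ModelSpec, TrainConfig, TrainedModel, build_model, predict, train
from .windowing import LabelScheme, WindowConfig, build_training_arrays

logger = logging.getLogger("semgrec")


# ---------------------------------------------------------------------------
# Fold planning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Disjoint subject groups; fold k tests group k, trains on the rest."""

    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        flat = [s for g in self.groups for s in g]
        if len(set(flat)) != len(flat):
            raise ValueError("groups must be pairwise disjoint")

    @property
    def subjects(self) -> set[str]:
        return {s for g in self.groups for s in g}

    @property
    def n_folds(self) -> int:
        return len(self.groups)

    def split(self, fold: int) -> tuple[set[str], set[str]]:
        """(train_subjects, test_subjects) for fold k."""
        test = set(self.groups[fold])
        train_subjects = self.subjects - test
        return train_subjects, test


def make_fold_plan(subjects, n_groups: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded random partition into near-equal groups (sizes differ <= 1)."""
    subjects = sorted(set(subjects))
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if len(subjects) < n_groups:
        raise ValueError(f"{len(subjects)} subjects cannot fill {n_groups} groups")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    groups = [tuple(sorted(part)) for part in np.array_split(np.asarray(order, dtype=object), n_groups)]
    return FoldPlan(groups=tuple(groups))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_matrix(
    true_classes, predicted_classes, n_classes: int = N_CLASSES
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized confusion matrix plus raw counts (rows = true class).

    Raw counts sum to the number of predictions; each nonempty row of the
    normalized matrix sums to 1 exactly.  Empty rows stay all-zero.
    """
    true_classes = np.asarray(true_classes, dtype=np.int64)
    predicted_classes = np.asarray(predicted_classes, dtype=np.int64)
    if true_classes.shape != predicted_classes.shape:
        raise ValueError("true and predicted label sequences differ in length")
    for arr, name in ((true_classes, "true"), (predicted_classes, "predicted")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} class index out of range [0, {n_classes})")
    counts = _sk_confusion(true_classes, predicted_classes, labels=np.arange(n_classes))
    row_sums = counts.sum(axis=1, keepdims=True)
    normalized = np.divide(
        counts, row_sums, out=np.zeros((n_classes, n_classes)), where=row_sums > 0
    )
    return normalized, counts


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    """Held-out metrics of one fold."""

    fold_id: int
    test_subjects: tuple[str, ...]
    test_accuracy: float
    confusion: np.ndarray  # row-normalized
    confusion_counts: np.ndarray
    history: dict[str, list[float]] = field(default_factory=dict)
    trained: TrainedModel | None = None


@dataclass
class CVReport:
    """Per-fold results with their aggregate accuracy."""

    scheme: LabelScheme
    folds: list[FoldResult]

    @property
    def accuracies(self) -> np.ndarray:
        return np.asarray([f.test_accuracy for f in self.folds])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": [f.fold_id for f in self.folds],
                "test_subjects": ["|".join(f.test_subjects) for f in self.folds],
                "test_accuracy": [f.test_accuracy for f in self.folds],
                "scheme": self.scheme.mode,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "scheme": self.scheme.mode,
                "epsilon": self.scheme.epsilon,
                "mean_accuracy": self.mean_accuracy,
                "std_accuracy": self.std_accuracy,
                "folds": [
                    {
                        "fold": f.fold_id,
                        "test_subjects": list(f.test_subjects),
                        "test_accuracy": f.test_accuracy,
                        "confusion": f.confusion.tolist(),
                    }
                    for f in self.folds
                ],
            },
            indent=2,
        )


def _fold_seed(base_seed: int, fold_id: int) -> int:
    """Stable per-fold seed; identical across label schemes (paired runs)."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(5, fold_id))
    return int(ss.generate_state(1)[0] % (2**31))


def _majority_vote_accuracy(window_set, pred_classes: np.ndarray) -> float:
    true, voted = [], []
    for rec_id in np.unique(window_set.recording_ids):
        rows = np.flatnonzero(window_set.recording_ids == rec_id)
        votes = np.bincount(pred_classes[rows], minlength=N_CLASSES)
        voted.append(int(votes.argmax()))
        true.append(int(window_set.labels[rows[0]]))
    return float(np.mean(np.asarray(true) == np.asarray(voted)))


def cross_validate(
    dataset: Dataset,
    window_config: WindowConfig = WindowConfig(),
    scheme: LabelScheme = LabelScheme(),
    train_config: TrainConfig = TrainConfig(),
    fold_plan: FoldPlan | None = None,
    model_spec: ModelSpec = ModelSpec(),
    validation_fraction: float = 0.25,
    majority_vote: bool = False,
    keep_models: bool = False,
    folds: "list[int] | None" = None,
) -> CVReport:
    """Leave-one-group-out cross-validation over subjects.

    For every fold the train/validation and test subject sets are asserted
    disjoint before any window reaches the model (no subject leakage).
    ``folds`` restricts the run to a subset of fold ids (useful for long
    schedules); by default every fold runs.
    """
    if fold_plan is None:
        fold_plan = make_fold_plan(dataset.subjects, seed=train_config.seed)
    missing = dataset.subjects - fold_plan.subjects
    if missing:
        raise ValueError(f"subjects missing from the fold plan: {sorted(missing)}")
    fold_ids = list(range(fold_plan.n_folds)) if folds is None else list(folds)
    results: list[FoldResult] = []
    for fold_id in fold_ids:
        train_subjects, test_subjects = fold_plan.split(fold_id)
        assert not (train_subjects & test_subjects), "subject leakage across fold"
        train_ws = build_training_arrays(dataset.subset(train_subjects), window_config, scheme)
        test_ws = build_training_arrays(dataset.subset(test_subjects), window_config, scheme)
        assert not (set(train_ws.subject_ids) & set(test_ws.subject_ids)), \
            "subject leakage between train and test windows"
        seed = _fold_seed(train_config.seed, fold_id)
        fold_config = TrainConfig(
            learning_rate=train_config.learning_rate,
            batch_size=train_config.batch_size,
            epochs=train_config.epochs,
            seed=seed,
        )
        net = build_model(model_spec, window_config.look_back, train_ws.X.shape[2], seed=seed)
        trained = train(net, train_ws, train_config=fold_config,
                        validation_fraction=validation_fraction)
        _, pred = predict(trained, test_ws.X)
        true = test_ws.labels
        if majority_vote:
            accuracy = _majority_vote_accuracy(test_ws, pred)
        else:
            accuracy = float((pred == true).mean())
        normalized, counts = confusion_matrix(true, pred)
        logger.info(
            "fold %d test subjects %s accuracy %.4f",
            fold_id, sorted(test_subjects), accuracy,
        )
        results.append(
            FoldResult(
                fold_id=fold_id,
                test_subjects=tuple(sorted(test_subjects)),
                test_accuracy=accuracy,
                confusion=normalized,
                confusion_counts=counts,
                history=trained.history,
                trained=trained if keep_models else None,
            )
        )
    return CVReport(scheme=scheme, folds=results)


@dataclass
class SchemeComparison:
    """Paired one-hot vs. label-smoothing cross-validation reports."""

    one_hot: CVReport
    smoothed: CVReport

    def to_frame(self) -> pd.DataFrame:
        rows = pd.concat([self.one_hot.to_frame(), self.smoothed.to_frame()],
                         ignore_index=True)
        return rows

    @property
    def per_fold_difference(self) -> np.ndarray:
        """smoothed minus one-hot test accuracy, per fold."""
        return self.smoothed.accuracies - self.one_hot.accuracies


def compare_label_schemes(
    dataset: Dataset,
    window_config: WindowConfig = WindowConfig(),
    train_config: TrainConfig = TrainConfig(),
    fold_plan: FoldPlan | None = None,
    model_spec: ModelSpec = ModelSpec(),
    epsilon: float = 0.01,
    validation_fraction: float = 0.25,
    folds: "list[int] | None" = None,
) -> SchemeComparison:
    """Run the identical CV twice, varying only the target encoding.

    Fold plan, windows and per-fold seeds (hence initial weights and batch
    order) are shared, so the scheme is the only difference between runs.
    """
    if fold_plan is None:
        fold_plan = make_fold_plan(dataset.subjects, seed=train_config.seed)
    one_hot = cross_validate(
        dataset, window_config, LabelScheme("one_hot"), train_config, fold_plan,
        model_spec, validation_fraction, folds=folds,
    )
    smoothed = cross_validate(
        dataset, window_config, LabelScheme("smoothed", epsilon=epsilon), train_config,
        fold_plan, model_spec, validation_fraction, folds=folds,
    )
    return SchemeComparison(one_hot=one_hot, smoothed=smoothed)


# ---------------------------------------------------------------------------
# Embedding export
# ---------------------------------------------------------------------------

def export_embedding(
    model: TrainedModel,
    windows: np.ndarray,
    labels: np.ndarray | None = None,
    subjects: np.ndarray | None = None,
    method: str = "tsne",
    seed: int = 0,
    perplexity: float = 30.0,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """2-D embedding of the penultimate (post-GRU, pre-head) representation.

    Delegates to scikit-learn's t-SNE; returns one (x, y) point per window
    with class and subject columns, optionally written as CSV.
    """
    if method != "tsne":
        raise ValueError(f"unknown embedding method {method!r}")
    from sklearn.manifold import TSNE

    windows = np.asarray(windows)
    if len(windows) <= perplexity:
        raise ValueError(
            f"t-SNE needs more windows than the perplexity ({perplexity}); got {len(windows)}"
        )
    features = model.model.embed(windows)
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(features.astype(np.float64))
    frame = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1]})
    if labels is not None:
        frame["class"] = [Gesture(int(c)).label for c in np.asarray(labels)]
    if subjects is not None:
        frame["subject"] = list(subjects)
    if path is not None:
        frame.to_csv(Path(path), index=False)
    return frame
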