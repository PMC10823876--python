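"""Gesture classification with a feed-forward (back-propagation) network.

A stratified 2:1 train/test split, a single-hidden-layer multilayer
perceptron with sigmoidal activation, and an evaluation report carrying
the overall accuracy, per-gesture accuracy and the confusion matrix.

The network hyperparameters are deliberately modest: one hidden layer of
2I + 1 units for I input features, logistic activation, trained to a
loss plateau with L-BFGS.  Recognition-quality comparisons in this
package are relative (with versus without channel augmentation), so any
fixed reasonable learner suffices as long as it is held constant across
arms; every knob is exposed in :class:`MLPConfig` and seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neural_network import MLPClassifier

from .features import LabeledFeatureSet

__all__ = [
    "SplitSpec",
    "MLPConfig",
    "TrainedClassifier",
    "EvaluationReport",
    "split",
    "train",
    "evaluate",
]


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split: default 2:1 (train fraction 2/3)."""

    train_fraction: float = 2.0 / 3.0
    per_class: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )


def split(
    fs: LabeledFeatureSet, spec: SplitSpec
) -> tuple[LabeledFeatureSet, LabeledFeatureSet]:
    """Seeded stratified split into disjoint, exhaustive train/test sets.

    Per class, ``round(J_k * train_fraction)`` rows go to train and the
    rest to test, after a seeded shuffle.  With ``per_class=False`` the
    rounding is applied to the whole set instead.
    """
    rng = np.random.default_rng(spec.seed)
    n = fs.labels.size
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    if spec.per_class:
        for k in fs.classes:
            rows = np.flatnonzero(fs.labels == k)
            if rows.size < 2:
                raise ValueError(
                    f"class {k} has only {rows.size} sample(s); "
                    "a per-class split needs at least 2"
                )
            perm = rng.permutation(rows)
            n_train = int(round(rows.size * spec.train_fraction))
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
    else:
        perm = rng.permutation(n)
        n_train = int(round(n * spec.train_fraction))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return fs.subset(tr), fs.subset(te)


@dataclass(frozen=True)
class MLPConfig:
    """Network hyperparameters; ``hidden_layers=None`` means one layer of
    2I + 1 units where I is the feature dimensionality."""

    hidden_layers: tuple[int, ...] | None = None
    activation: str = "logistic"
    solver: str = "lbfgs"
    max_epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers is not None:
            if len(self.hidden_layers) == 0 or any(
                w < 1 for w in self.hidden_layers
            ):
                raise ValueError("hidden layer widths must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass(frozen=True)
class TrainedClassifier:
    """A fitted network plus the configuration and label order it used."""

    model: MLPClassifier
    config: MLPConfig
    classes: np.ndarray
    n_features: int
    n_train: int

    def predict(self, matrix: np.ndarray) -> np.ndarray:
        """Predicted gesture ids; ties on class scores break toward the
        lowest class id (the order of ``classes``)."""
        matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
        if matrix.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {matrix.shape[1]} does not match the "
                f"model ({self.n_features})"
            )
        scores = self.model.predict_proba(matrix)
        # argmax returns the first maximum, i.e. the lowest class id
        return self.classes[np.argmax(scores, axis=1)]


def train(train_set: LabeledFeatureSet, cfg: MLPConfig = MLPConfig()) -> TrainedClassifier:
    """Fit the back-propagation network on a training feature set.

    Seeded and repeatable on the same platform; raises on a single-class
    training set.
    """
    classes = train_set.classes
    if classes.size < 2:
        raise ValueError(
            f"training needs >= 2 classes, got {classes.size}"
        )
    hidden = cfg.hidden_layers or (2 * train_set.n_features + 1,)
    model = MLPClassifier(
        hidden_layer_sizes=hidden,
        activation=cfg.activation,
        solver=cfg.solver,
        max_iter=cfg.max_epochs,
        learning_rate_init=cfg.learning_rate,
        random_state=cfg.seed,
    )
    import warnings

    with warnings.catch_warnings():
        # a capped optimizer may stop at max_epochs without converging;
        # that is the configured behaviour, not a defect
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(train_set.matrix, train_set.labels)
    return TrainedClassifier(
        model=model,
        config=cfg,
        classes=np.asarray(model.classes_),
        n_features=train_set.n_features,
        n_train=train_set.labels.size,
    )


@dataclass(frozen=True)
class EvaluationReport:
    """Test-set recognition quality.

    ``confusion[r, c]`` counts test windows of true class ``classes[r]``
    predicted as ``classes[c]``; row sums equal the per-class test
    counts and ``overall_accuracy`` equals trace/total.
    """

    classes: np.ndarray
    confusion: np.ndarray
    overall_accuracy: float
    per_class_accuracy: dict = field(default_factory=dict)
    n_train: int = 0
    n_test: int = 0


def evaluate(clf: TrainedClassifier, test_set: LabeledFeatureSet) -> EvaluationReport:
    """Accuracy and confusion matrix of a fitted classifier on a test set."""
    if test_set.labels.size == 0:
        raise ValueError("test set is empty")
    if test_set.n_features != clf.n_features:
        raise ValueError(
            f"test feature dimension {test_set.n_features} does not match "
            f"the model ({clf.n_features})"
        )
    pred = clf.predict(test_set.matrix)
    labels = np.union1d(clf.classes, test_set.classes)
    conf = _sk_confusion(test_set.labels, pred, labels=labels)
    total = conf.sum()
    acc = float(np.trace(conf) / total)
    per_class = {}
    for r, k in enumerate(labels):
        row_total = conf[r].sum()
        if row_total > 0:
            per_class[int(k)] = float(conf[r, r] / row_total)
    return EvaluationReport(
        classes=labels,
        confusion=conf,
        overall_accuracy=acc,
        per_class_accuracy=per_class,
        n_train=clf.n_train,
        n_test=int(total),
    )
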