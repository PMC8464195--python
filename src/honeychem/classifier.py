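"""Feed-forward neural classifier over the 68 sample classes.

A small fully-connected network (two rectifier hidden layers with inverted
dropout, softmax output, cross-entropy loss, Adam updates) maps a feature
row to a distribution over the sample classes. Training holds back a slice
of the training data for early stopping and restores the best weights, and
is fully deterministic under a seed.

Evaluation follows the study's protocol: stratified k-fold (6 folds by
default) over the augmented matrix, reporting per-fold accuracy on the
held-out fold only, their mean, and a pooled confusion matrix, separately
for three feature sets (sugars, organics, combined).
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix


@dataclass(frozen=True)
class ClassifierConfig:
    hidden_sizes: tuple[int, ...] = (128, 64)
    dropout: float = 0.2
    activation: str = "relu"
    learning_rate: float = 2e-3
    lr_decay: str = "cosine"  # "cosine" anneals to ~0 over max_epochs
    batch_size: int = 256
    max_epochs: int = 60
    patience: int = 10
    label_smoothing: float = 0.0
    # width (in grid cells, per channel) of a fixed max-pooling input stage
    # that makes organic features tolerant of Rf drift; 0 disables it
    organic_pool_cells: int = 0
    val_fraction: float = 0.1
    folds: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ValueError("label_smoothing must be in [0, 1)")
        if any(h <= 0 for h in self.hidden_sizes) or self.batch_size <= 0:
            raise ValueError("sizes must be positive")
        if self.activation != "relu":
            raise ValueError("only rectifier activation is implemented")
        if self.lr_decay not in ("cosine", "constant"):
            raise ValueError("lr_decay must be 'cosine' or 'constant'")
        if self.organic_pool_cells < 0:
            raise ValueError("organic_pool_cells must be non-negative")


@dataclass
class ClassifierReport:
    feature_set: str
    fold_accuracies: list[float]  # percent
    fold_sizes: list[int]
    mean_accuracy: float  # percent
    confusion: np.ndarray  # true x predicted counts, pooled over folds
    classes: list[str]

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "fold_accuracies": self.fold_accuracies,
            "fold_sizes": self.fold_sizes,
            "mean_accuracy": self.mean_accuracy,
            "confusion": self.confusion.tolist(),
            "classes": self.classes,
        }


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def pool_segments(matrix: FeatureMatrix, width: int) -> list[np.ndarray]:
    """Column groups for the drift-tolerant max-pooling input stage: each
    channel's grid columns in Rf order, chopped into windows of ``width``
    cells; sugar columns pass through as singleton groups."""
    if width <= 0:
        raise ValueError("pool width must be positive")
    segments = []
    for ch in matrix.channels():
        idx = matrix.organic_indices(ch)
        order = np.argsort([matrix.features[i].rf for i in idx])
        idx = idx[order]
        segments.extend(idx[s : s + width] for s in range(0, idx.size, width))
    segments.extend(np.array([i]) for i in matrix.sugar_indices())
    return segments


class NeuralClassifier:
    """Numpy multilayer perceptron fitted by :func:`train_classifier`.

    ``segments``, when given, defines a fixed max-pooling input stage (see
    :func:`pool_segments`): every feature group is reduced to its maximum
    before the first weight layer, which makes band intensities insensitive
    to small Rf drift.
    """

    def __init__(self, classes: list, config: ClassifierConfig, segments=None):
        self.classes = list(classes)
        self.config = config
        self.segments = None if segments is None else [np.asarray(s) for s in segments]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []

    def _apply_pool(self, X: np.ndarray) -> np.ndarray:
        if self.segments is None:
            return X
        return np.column_stack([X[:, seg].max(axis=1) for seg in self.segments])

    # -- internals ---------------------------------------------------------
    def _init_params(self, n_features: int, rng: np.random.Generator) -> None:
        sizes = (n_features, *self.config.hidden_sizes, len(self.classes))
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(
                (scale * rng.standard_normal((fan_in, fan_out))).astype(np.float32)
            )
            self.biases.append(np.zeros(fan_out, dtype=np.float32))

    def _forward(self, X, rng=None):
        """Returns activations per layer; applies dropout when rng is given."""
        acts = [X]
        masks = []
        h = X
        p = self.config.dropout
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            if i < len(self.weights) - 1:
                h = np.maximum(z, 0.0)
                if rng is not None and p > 0:
                    mask = (rng.random(h.shape) >= p).astype(np.float32) / (1.0 - p)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                h = z
            acts.append(h)
        return acts, masks

    def _loss(self, X, y_idx) -> float:
        probs = _softmax(self._forward(X)[0][-1].astype(np.float64))
        return float(-np.log(probs[np.arange(len(y_idx)), y_idx] + 1e-12).mean())

    # -- public API --------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.shape[1] != getattr(self, "_n_features_in", X.shape[1]):
            raise ValueError("feature count differs from the fitted matrix")
        X = self._apply_pool(X)
        if hasattr(self, "_keep"):
            X = X[:, self._keep]
        X = np.ascontiguousarray(X)
        return _softmax(self._forward(X)[0][-1].astype(np.float64))

    def predict(self, X: np.ndarray) -> list:
        idx = np.argmax(self.predict_proba(X), axis=1)
        return [self.classes[i] for i in idx]

    def fit(self, X: np.ndarray, y: list) -> "NeuralClassifier":
        cfg = self.config
        X = np.asarray(X, dtype=np.float32)
        if not np.isfinite(X).all():
            raise ValueError("non-finite inputs")
        self._n_features_in = X.shape[1]
        X = self._apply_pool(X)
        # constant columns (e.g. never-occupied grid positions) carry no
        # information; dropping them saves most of the matmul cost
        self._keep = np.flatnonzero(np.ptp(X, axis=0) > 0)
        if self._keep.size == 0:
            self._keep = np.arange(X.shape[1])
        X = np.ascontiguousarray(X[:, self._keep])
        class_index = {c: i for i, c in enumerate(self.classes)}
        try:
            y_idx = np.array([class_index[c] for c in y])
        except KeyError as err:
            raise ValueError(f"unknown class {err.args[0]!r}") from err
        missing = set(range(len(self.classes))) - set(y_idx.tolist())
        if missing:
            names = [str(self.classes[i]) for i in sorted(missing)]
            raise ValueError(f"classes absent from training set: {names}")

        rng = np.random.default_rng(cfg.seed)
        self._init_params(X.shape[1], rng)

        # held-back slice of the training data for early stopping
        order = rng.permutation(len(y_idx))
        n_val = max(1, int(round(cfg.val_fraction * len(y_idx))))
        val, train = order[:n_val], order[n_val:]
        if train.size == 0:
            train, val = order, order
        Xt, yt, Xv, yv = X[train], y_idx[train], X[val], y_idx[val]

        m = [np.zeros_like(w) for w in self.weights + self.biases]
        v = [np.zeros_like(w) for w in self.weights + self.biases]
        best = ([w.copy() for w in self.weights], [b.copy() for b in self.biases])
        best_loss = np.inf
        since_best = 0
        step = 0
        b1, b2, eps = 0.9, 0.999, 1e-8
        n_layers = len(self.weights)

        for epoch in range(cfg.max_epochs):
            if cfg.lr_decay == "cosine":
                base_lr = cfg.learning_rate * 0.5 * (
                    1.0 + np.cos(np.pi * epoch / max(1, cfg.max_epochs - 1))
                )
            else:
                base_lr = cfg.learning_rate
            perm = rng.permutation(len(yt))
            for start in range(0, len(yt), cfg.batch_size):
                batch = perm[start : start + cfg.batch_size]
                xb, yb = Xt[batch], yt[batch]
                acts, masks = self._forward(xb, rng=rng)
                probs = _softmax(acts[-1].astype(np.float64))
                delta = probs
                ls = cfg.label_smoothing
                if ls > 0.0:
                    delta -= ls / len(self.classes)
                    delta[np.arange(len(yb)), yb] -= 1.0 - ls - ls / len(self.classes)
                else:
                    delta[np.arange(len(yb)), yb] -= 1.0
                delta = (delta / len(yb)).astype(np.float32)
                grads_w, grads_b = [None] * n_layers, [None] * n_layers
                for i in range(n_layers - 1, -1, -1):
                    grads_w[i] = acts[i].T @ delta
                    grads_b[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = delta @ self.weights[i].T
                        delta *= acts[i] > 0
                        if masks[i - 1] is not None:
                            delta *= masks[i - 1]
                step += 1
                params = self.weights + self.biases
                grads = grads_w + grads_b
                lr_t = base_lr * np.sqrt(1 - b2**step) / (1 - b1**step)
                for j, (p, g) in enumerate(zip(params, grads)):
                    m[j] = b1 * m[j] + (1 - b1) * g
                    v[j] = b2 * v[j] + (1 - b2) * g * g
                    p -= lr_t * m[j] / (np.sqrt(v[j]) + eps)
            val_loss = self._loss(Xv, yv)
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best = ([w.copy() for w in self.weights], [b.copy() for b in self.biases])
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        self.weights, self.biases = best
        return self


def train_classifier(
    matrix: FeatureMatrix,
    labels: list | None = None,
    config: ClassifierConfig | None = None,
    classes: list | None = None,
) -> NeuralClassifier:
    """Train the network on the whole matrix; deterministic under the seed.

    ``classes`` fixes the output class set (every class must appear in the
    training labels); by default the distinct labels present are used, in
    sorted order.
    """
    config = config or ClassifierConfig()
    labels = list(matrix.labels) if labels is None else list(labels)
    if len(labels) != matrix.n_samples:
        raise ValueError("label count must match row count")
    if classes is None:
        classes = sorted(set(labels), key=str)
    segments = (
        pool_segments(matrix, config.organic_pool_cells)
        if config.organic_pool_cells
        else None
    )
    model = NeuralClassifier(classes, config, segments=segments)
    return model.fit(matrix.values, labels)


def confusion_matrix(true: list, predicted: list, classes: list) -> np.ndarray:
    """Counts of true class i predicted as j; trace/total is the accuracy."""
    if len(true) != len(predicted):
        raise ValueError("label sequences differ in length")
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true, predicted):
        if t not in index or p not in index:
            raise ValueError(f"unknown label {t if t not in index else p!r}")
        cm[index[t], index[p]] += 1
    return cm


def kfold_evaluate(
    matrix: FeatureMatrix,
    labels: list | None = None,
    config: ClassifierConfig | None = None,
    feature_set: str = "combined",
) -> ClassifierReport:
    """Stratified k-fold accuracy and pooled confusion for one feature set.

    Every sample is tested exactly once across the folds; fold accuracies
    are percentages on the held-out fold only.
    """
    config = config or ClassifierConfig()
    labels = list(matrix.labels) if labels is None else list(labels)
    sub = matrix.select(feature_set)
    classes = sorted(set(labels), key=str)
    y = np.array([str(l) for l in labels], dtype=object)
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    fold_seeds = np.random.SeedSequence(config.seed).generate_state(config.folds)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_accuracies = []
    fold_sizes = []
    segments = (
        pool_segments(sub, config.organic_pool_cells)
        if config.organic_pool_cells
        else None
    )
    for fold, (train, test) in enumerate(skf.split(sub.values, y)):
        fold_cfg = ClassifierConfig(
            **{**config.__dict__, "seed": int(fold_seeds[fold] % 2**31)}
        )
        model = NeuralClassifier(classes, fold_cfg, segments=segments)
        model.fit(sub.values[train], [labels[i] for i in train])
        pred = model.predict(sub.values[test])
        truth = [labels[i] for i in test]
        confusion += confusion_matrix(truth, pred, classes)
        acc = 100.0 * np.mean([p == t for p, t in zip(pred, truth)])
        fold_accuracies.append(float(acc))
        fold_sizes.append(len(test))
    return ClassifierReport(
        feature_set=feature_set,
        fold_accuracies=fold_accuracies,
        fold_sizes=fold_sizes,
        mean_accuracy=float(np.mean(fold_accuracies)),
        confusion=confusion,
        classes=[str(c) for c in classes],
    )
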