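import numpy as np
import pytest

from honeychem import (
    AugmentationConfig,
    GridSpec,
    StudyDesignConfig,
    assemble_features,
    augment,
    generate_study,
    restrict_rf_window,
    standardise,
)
from honeychem.classifier import (
    ClassifierConfig,
    NeuralClassifier,
    confusion_matrix,
    kfold_evaluate,
    train_classifier,
)

from conftest import matrix_from_values


def two_class_toy(n=60, gap=8.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n // 2, 3))
    b = rng.normal(gap, 1, (n // 2, 3))
    X = np.vstack([a, b])
    y = ["A"] * (n // 2) + ["B"] * (n // 2)
    return matrix_from_values(X), y


def small_augmented_study(seed=0, outer=2, inner=5, grid_step=0.01):
    table = generate_study(StudyDesignConfig(seed=seed))
    matrix = assemble_features(restrict_rf_window(table), GridSpec(step=grid_step))
    aug = augment(matrix, AugmentationConfig(outer_repeats=outer, inner_repeats=inner, seed=seed + 1))
    return standardise(aug)


def test_config_validation():
    with pytest.raises(ValueError):
        ClassifierConfig(folds=1)
    with pytest.raises(ValueError):
        ClassifierConfig(dropout=1.0)
    with pytest.raises(ValueError):
        ClassifierConfig(hidden_sizes=(0,))
    with pytest.raises(ValueError):
        ClassifierConfig(activation="tanh")


def test_training_is_deterministic_under_seed():
    matrix, y = two_class_toy()
    cfg = ClassifierConfig(hidden_sizes=(16,), max_epochs=10, seed=5)
    m1 = train_classifier(matrix, y, cfg)
    m2 = train_classifier(matrix, y, cfg)
    np.testing.assert_array_equal(
        m1.predict_proba(matrix.values), m2.predict_proba(matrix.values)
    )


def test_separable_toy_reaches_full_training_accuracy():
    matrix, y = two_class_toy()
    cfg = ClassifierConfig(
        hidden_sizes=(16,), learning_rate=5e-3, batch_size=8,
        max_epochs=80, patience=80, seed=1,
    )
    model = train_classifier(matrix, y, cfg)
    assert model.predict(matrix.values) == y


def test_missing_class_and_nonfinite_inputs_are_rejected():
    matrix, y = two_class_toy()
    cfg = ClassifierConfig(hidden_sizes=(8,), max_epochs=2, seed=0)
    model = NeuralClassifier(["A", "B", "C"], cfg)
    with pytest.raises(ValueError, match="absent"):
        model.fit(matrix.values, y)
    bad = matrix.values.copy()
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        NeuralClassifier(["A", "B"], cfg).fit(bad, y)


def test_confusion_matrix_definition():
    classes = ["A", "B", "C"]
    cm = confusion_matrix(["A", "B", "C", "A"], ["A", "B", "C", "A"], classes)
    assert np.trace(cm) == 4 and cm.sum() == 4
    cm2 = confusion_matrix(["A", "A", "B"], ["B", "A", "B"], classes)
    assert cm2[0, 1] == 1 and np.trace(cm2) == 2
    assert np.trace(cm2) / cm2.sum() == pytest.approx(2 / 3)
    with pytest.raises(ValueError, match="unknown"):
        confusion_matrix(["A"], ["D"], classes)
    with pytest.raises(ValueError, match="length"):
        confusion_matrix(["A"], ["A", "B"], classes)


def test_kfold_partition_and_pooled_accuracy_consistency():
    std = small_augmented_study()
    cfg = ClassifierConfig(hidden_sizes=(32,), max_epochs=15, patience=15, folds=3, seed=2)
    report = kfold_evaluate(std, config=cfg, feature_set="sugars")
    assert len(report.fold_accuracies) == 3
    assert report.confusion.sum() == std.n_samples  # every sample tested once
    # row sums equal per-class counts
    from collections import Counter

    counts = Counter(str(l) for l in std.labels)
    for i, cls in enumerate(report.classes):
        assert report.confusion[i].sum() == counts[cls]
    # pooled-confusion accuracy equals the sample-weighted fold mean
    pooled = 100 * np.trace(report.confusion) / report.confusion.sum()
    weighted = np.average(report.fold_accuracies, weights=report.fold_sizes)
    assert pooled == pytest.approx(weighted, abs=1e-6)
    assert report.mean_accuracy == pytest.approx(np.mean(report.fold_accuracies))


def test_constant_features_give_majority_rate_accuracy():
    rng = np.random.default_rng(0)
    X = np.ones((120, 3))
    y = ["A"] * 60 + ["B"] * 60
    matrix = matrix_from_values(X)
    cfg = ClassifierConfig(hidden_sizes=(8,), max_epochs=5, folds=3, seed=0)
    report = kfold_evaluate(matrix, labels=y, config=cfg, feature_set="combined")
    assert report.mean_accuracy <= 65.0  # ~50% majority rate, no signal


def test_combined_features_at_least_as_accurate_as_single_sets():
    """Across 5 seeds, the combined feature set must match or beat sugars-only
    and organics-only (within a small one-sided tolerance)."""
    means = {"sugars": [], "organics": [], "combined": []}
    for seed in range(5):
        std = small_augmented_study(seed=seed)
        cfg = ClassifierConfig(
            hidden_sizes=(64, 32), max_epochs=25, patience=25, folds=3, seed=seed
        )
        for fs in means:
            means[fs].append(kfold_evaluate(std, config=cfg, feature_set=fs).mean_accuracy)
    combined = np.mean(means["combined"])
    assert combined + 1.0 >= np.mean(means["sugars"])
    assert combined + 1.0 >= np.mean(means["organics"])
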