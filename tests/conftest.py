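import numpy as np
import pytest

from honeychem import (
    FeatureMatrix,
    GridSpec,
    StudyDesignConfig,
    assemble_features,
    generate_study,
    restrict_rf_window,
    standardise,
)
from honeychem.features import FeatureInfo
from honeychem.labels import SampleLabel


@pytest.fixture(scope="session")
def study_table():
    return generate_study(StudyDesignConfig(seed=1))


@pytest.fixture(scope="session")
def feature_matrix(study_table):
    return assemble_features(restrict_rf_window(study_table), GridSpec())


@pytest.fixture(scope="session")
def std_matrix(feature_matrix):
    return standardise(feature_matrix)


def matrix_from_values(values, labels=None) -> FeatureMatrix:
    """Bare numeric matrix wrapped as sugar-free organic features on one
    channel, for clustering/PCA tests that only care about the geometry."""
    values = np.asarray(values, dtype=float)
    features = [
        FeatureInfo("organic", f"R254@{0.05 + 0.005 * j:.4f}", channel="R254", rf=0.05 + 0.005 * j)
        for j in range(values.shape[1])
    ]
    labels = labels or [SampleLabel("MAN")] * values.shape[0]
    return FeatureMatrix(values, features, list(labels))
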