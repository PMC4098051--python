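import numpy as np
import pytest

import pneumotex as px


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_rois():
    """40 ROIs (20 normal, 20 abnormal across conditions) for classifier and
    evaluation tests."""
    cfgs = px.default_study_configs()
    normals, _ = px.gen_dataset(cfgs[:1], 20, seed=11)
    abnormals, _ = px.gen_dataset(cfgs[1:], 4, seed=11)
    return normals + abnormals


@pytest.fixture(scope="session")
def small_features(small_rois):
    """Full feature vectors of the 40-ROI set, keyed by ROI id."""
    return {r.id: px.build_feature_vector(r) for r in small_rois}


@pytest.fixture(scope="session")
def small_labels(small_rois):
    return {r.id: r.label == "abnormal" for r in small_rois}
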