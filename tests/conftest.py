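import numpy as np
import pytest

from palatemark.config import PipelineConfig
from palatemark.mesh_io import mesh_to_pointcloud
from palatemark.preprocess import preprocess_cloud
from palatemark.synthetic import CastShapeParams, generate_cast


@pytest.fixture(scope="session")
def small_cast():
    """One deterministic synthetic cast at test density."""
    return generate_cast(CastShapeParams(seed=7))


@pytest.fixture(scope="session")
def prepared_small(small_cast):
    """Preprocessed (oriented, normalized, 2048-point) version of small_cast."""
    mesh, lms = small_cast
    cloud = mesh_to_pointcloud(mesh)
    sampled, tf, lms_norm = preprocess_cloud(cloud, 2048, lms)
    return sampled, tf, lms_norm, lms


@pytest.fixture(scope="session")
def scaled_config():
    return PipelineConfig.scaled_down(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
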