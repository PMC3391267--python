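import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import facemvpa as fm

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_geometry() -> fm.Geometry:
    """Reduced grid with two compact ROIs, for fast end-to-end tests."""
    return fm.Geometry(
        shape=(12, 12, 6),
        rois={
            "ffa_like": fm.RoiSpec(center=(3, 3, 3), n_voxels=10),
            "ofa_like": fm.RoiSpec(center=(8, 8, 3), n_voxels=12),
        },
    )


@pytest.fixture(scope="session")
def small_design_params() -> fm.DesignParams:
    return fm.DesignParams(n_veridical=12, n_scrambled=12, n_fixation=4)


@pytest.fixture(scope="session")
def tiny_config(small_geometry, small_design_params) -> fm.PipelineConfig:
    return fm.PipelineConfig(
        master_seed=7,
        n_subjects=3,
        n_runs=4,
        scenario="holistic",
        design=small_design_params,
        geometry=small_geometry,
    )


@pytest.fixture(scope="session")
def noiseless() -> fm.NoiseModel:
    return fm.NoiseModel(sigma_thermal=0.0, ar1_coef=0.0, drift_amp=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
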