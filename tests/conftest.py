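import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petiq import AcquisitionConfig, PhantomSpec, build_nema_phantom

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec_41() -> PhantomSpec:
    """4:1 sphere-to-background phantom filling."""
    return PhantomSpec.for_ratio("4:1")


@pytest.fixture(scope="session")
def coarse_acq() -> AcquisitionConfig:
    """Fast 4 mm isotropic acquisition used for statistical tests."""
    return AcquisitionConfig(voxel_size_mm=(4.0, 4.0, 4.0), time_per_bed_s=180.0, seed=0)


@pytest.fixture(scope="session")
def coarse_truth(spec_41, coarse_acq):
    return build_nema_phantom(spec_41, coarse_acq.voxel_size_mm)
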