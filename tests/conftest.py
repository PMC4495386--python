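import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20150708)


@pytest.fixture(scope="session")
def study_dataset():
    """One synthetic run of the full study design: 30 colonies x 2 treatments."""
    from nestquorum.colonies import ExperimentDesign, generate_dataset, records_to_frame

    records = generate_dataset(ExperimentDesign(), seed=11)
    return records_to_frame(records)
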