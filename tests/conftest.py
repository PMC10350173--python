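import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="dropping zero-variance")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Two-group cohort with one planted module and background regions."""
    from cofosnet.simulate import CountSimConfig, GroupSpec, ModuleSpec, simulate_counts

    cfg = CountSimConfig(
        n_regions=30,
        n_subjects_per_group=15,
        groups=(GroupSpec("AGG", "male"), GroupSpec("NON", "male")),
        module_spec=(ModuleSpec("pink", 10, 0.6),),
        group_module_effects={("AGG:male", "pink"): 1.5},
        seed=77,
    )
    return simulate_counts(cfg), cfg
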