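import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from voxelight.synthetic import (  # noqa: E402
    EffectRegion,
    SynthConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with one strongly planted region, shared across tests."""
    config = SynthConfig(
        n_per_group=40,
        effect_regions=[EffectRegion("temporal", (9, 9, 12), 6.0, -1.2)],
        cognitive_weights={
            "executive_function": {"temporal": 0.6},
            "processing_speed": {"temporal": 0.5},
        },
        seed=11,
    )
    phen, vols, cog, truth = generate_cohort(config)
    return config, phen, vols, cog, truth


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effects anywhere: group labels carry no signal."""
    config = SynthConfig(
        n_per_group=40,
        effect_regions=[EffectRegion("temporal", (9, 9, 12), 6.0, 0.0)],
        cognitive_weights={},
        age_shift_years=0.0,
        seed=13,
    )
    phen, vols, cog, truth = generate_cohort(config)
    return config, phen, vols, cog, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
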