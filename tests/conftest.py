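import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_plant():
    """One rendered mid-size plant with its ground truth (shared, read-only)."""
    from phenoshoot import synthetic

    spec = synthetic.PlantSpec(seed=3)
    images, truth = synthetic.generate_plant_images(spec)
    return spec, images, truth


@pytest.fixture(scope="session")
def noisefree_plant():
    from phenoshoot import synthetic

    spec = synthetic.PlantSpec(texture_noise=0.0, seed=3)
    images, truth = synthetic.generate_plant_images(spec)
    return spec, images, truth


@pytest.fixture(scope="session")
def watering_cohort():
    """Pooled daily-imaged cohort from the sigmoidal watering-trial design."""
    from phenoshoot import synthetic

    series = synthetic.generate_growth_series(synthetic.TrajectorySpec(seed=8))
    t = np.concatenate([s.times for s in series])
    y = np.concatenate([s.values for s in series])
    return t, y


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
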