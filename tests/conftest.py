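import numpy as np
import pytest

from ecgqc import (
    ClassifierConfig,
    DeviceProfile,
    NoiseEpisode,
    SynthRecipe,
    find_reference_template,
    generate_clean_ecg,
    simulate,
)


@pytest.fixture(scope="session")
def device():
    return DeviceProfile()


@pytest.fixture(scope="session")
def cfg():
    return ClassifierConfig()


@pytest.fixture(scope="session")
def clean_recipe():
    return SynthRecipe(duration_s=60.0, seed=11)


@pytest.fixture(scope="session")
def clean_signal(clean_recipe):
    return generate_clean_ecg(clean_recipe)


@pytest.fixture(scope="session")
def clean_template(clean_signal):
    return find_reference_template(clean_signal)


@pytest.fixture(scope="session")
def mixed_result():
    """60 s recording exercising every artifact class."""
    recipe = SynthRecipe(
        duration_s=60.0,
        seed=17,
        episodes=(
            NoiseEpisode("saturation", 20.0, 10.0),
            NoiseEpisode("flatline", 30.0, 10.0),
            NoiseEpisode("muscle", 40.0, 10.0),
            NoiseEpisode("baseline_wander", 50.0, 10.0),
        ),
    )
    return simulate(recipe)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
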