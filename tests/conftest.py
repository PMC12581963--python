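import pytest

from pacesense.looping import loop_episode
from pacesense.synth import VfModelParams, generate_episode_library, generate_vf_episode


@pytest.fixture(scope="session")
def small_library():
    """Ten synthetic VF episodes spanning the sensed-amplitude range."""
    return generate_episode_library(10, (0.15, 1.0), seed=1)


@pytest.fixture(scope="session")
def small_library_looped(small_library):
    return [loop_episode(e, 60.0) for e in small_library]


@pytest.fixture(scope="session")
def full_library_looped():
    """The 100-episode study library (amplitudes 0.15-1.0 mV), looped to 60 s."""
    lib = generate_episode_library(100, (0.15, 1.0), seed=1)
    return [loop_episode(e, 60.0) for e in lib]


@pytest.fixture()
def reference_episode():
    """One mid-amplitude episode for single-episode signal tests."""
    return generate_vf_episode(VfModelParams(target_mean_amp_mv=0.5, duration_s=8.0, seed=3))
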