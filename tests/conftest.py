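import numpy as np
import pytest

from nirsnet import (
    EventEntry,
    EventSchedule,
    GroupProfile,
    NoiseSpec,
    default_montage,
    make_default_schedule,
    uniform_connectivity,
)

FS = 7.81


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def schedule():
    return make_default_schedule()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_schedule():
    """Three-trial paradigm with a 60-s resting state, for fast tests."""
    entries = []
    for k in range(3):
        t0 = 60.0 + k * 38.0
        entries += [
            EventEntry(t0 - 2.0, 2.0, "ready"),
            EventEntry(t0, 8.0, "encode"),
            EventEntry(t0 + 8.0, 14.0, "retain"),
            EventEntry(t0 + 22.0, 2.0, "probe"),
            EventEntry(t0 + 24.0, 14.0, "rest"),
        ]
    segments = {"resting": (0.0, 60.0), "task": (60.0, 174.0), "post_rest": (174.0, 194.0)}
    return EventSchedule(entries=entries, segments=segments)


@pytest.fixture
def quiet_profile():
    """Noise-free, background-free profile: pure evoked signal."""
    return GroupProfile(
        label="quiet",
        activation_amplitude=0.4,
        active_channels=(0, 1, 5),
        latent_connectivity=uniform_connectivity(20, 0.4),
        noise=NoiseSpec.silent(),
        background_sd=0.0,
        subject_cv=0.0,
    )
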