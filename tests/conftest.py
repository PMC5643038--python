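import numpy as np
import pytest

from liftbn import (
    PostureSpec,
    PostureStdDev,
    RandomScenario,
    SampleSet,
    SegmentParameterTable,
    Subject,
    fixture_path,
    load_config,
)

#: Frozen seed used by every seeded test in the suite.
SEED = 2017


@pytest.fixture(scope="session")
def subject():
    return Subject(stature=1.618, body_mass=65.6)


@pytest.fixture(scope="session")
def table():
    return SegmentParameterTable.default()


@pytest.fixture(scope="session")
def carbon_posture():
    return PostureSpec(ankle_deg=82, knee_deg=114, torso_deg=40, shoulder_deg=192, elbow_deg=-56)


@pytest.fixture(scope="session")
def carbon_sds():
    return PostureStdDev(ankle_deg=9.4, knee_deg=9.4, torso_deg=6.3, shoulder_deg=7.9, elbow_deg=11.8)


@pytest.fixture(scope="session")
def carbon_scenario(carbon_posture, carbon_sds, subject):
    return RandomScenario(
        posture_means=carbon_posture,
        posture_sds=carbon_sds,
        hand_mass_mean=53.1,
        hand_mass_sd=12.8,
        subject=subject,
        n_iterations=200_000,
        seed=SEED,
    )


@pytest.fixture(scope="session")
def fixture_config():
    return load_config(fixture_path("carbon_lifting"))


def make_sample_set(values, weights=None, seed=0):
    """Minimal SampleSet over a bare compression (and shear) array."""
    values = np.asarray(values, dtype=float)
    weights = np.ones_like(values) if weights is None else np.asarray(weights, dtype=float)
    return SampleSet(
        inputs={},
        outputs={"compression": values, "shear": values.copy()},
        weights=weights,
        seed=seed,
    )
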