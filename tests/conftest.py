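import numpy as np
import pytest

from spiroqc import (
    DEFAULT_CONFIG,
    CleanParams,
    compute_indices,
    generate_clean,
)


@pytest.fixture(scope="session")
def cfg():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def clean_maneuver():
    """Reference clean maneuver: FVC 4 L, PEF 8 L/s, 8 s exhalation."""
    return generate_clean(CleanParams(fvc=4.0, pef=8.0, rise_time=0.1, duration=8.0))


@pytest.fixture(scope="session")
def clean_indices(clean_maneuver, cfg):
    return compute_indices(clean_maneuver, cfg)


def random_clean_params(rng):
    """One draw from the documented physiological ranges (PEF conditioned on
    FVC as in the labeled-dataset generator)."""
    fvc = rng.uniform(2.0, 6.0)
    pef = float(np.clip(fvc * rng.uniform(1.5, 2.5), 4.0, 12.0))
    return CleanParams(
        fvc=fvc,
        pef=pef,
        rise_time=rng.uniform(0.08, 0.15),
        duration=rng.uniform(7.0, 10.0),
    )
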