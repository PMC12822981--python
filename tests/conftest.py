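from __future__ import annotations

import numpy as np
import pytest

from texent.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small strong-preset cohort: 3+3 patients x 2 images, 32 px."""
    cfg = SyntheticConfig(
        n_patients_regular=3,
        n_patients_irregular=3,
        images_per_patient=2,
        image_size=32,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def checkerboard():
    return (np.indices((32, 32)).sum(axis=0) % 2) * 255.0


@pytest.fixture()
def noise_image(rng):
    return rng.uniform(0.0, 255.0, (32, 32))
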