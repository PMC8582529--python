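import numpy as np
import pytest

from qfibrec.synthetic import (
    CohortSimParams,
    SimImageParams,
    generate_cohort,
    generate_sample,
)
from qfibrec.taxonomy import DEFAULT_TAXONOMY


@pytest.fixture(scope="session")
def taxonomy():
    return DEFAULT_TAXONOMY


@pytest.fixture(scope="session")
def mixed_sample():
    """Small mosaic with fibers in every region plus aggregate patches."""
    params = SimImageParams(
        tile_px=256,
        pixel_size_um=1.0,
        n_tiles=2,
        fibers_per_region={"portal": 3, "septal": 2, "fibrillar": 5},
        aggregate_patch_count=3,
        noise_sd=2.0,
        seed=11,
    )
    return params, generate_sample(params)


@pytest.fixture(scope="session")
def cohort64():
    data = generate_cohort(CohortSimParams(seed=7))
    labels = np.array([r.early_recurrence for r in data.records])
    return data, labels
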