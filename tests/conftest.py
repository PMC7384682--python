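import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/reference.py importable

from twocalm.localizations import LocalizationCloud
from twocalm.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def csr_cloud():
    """2000-point CSR cloud in a (1000 nm)^3 box."""
    return generate(SyntheticSpec(kind="csr", n_points=2000, box=(1000, 1000, 1000), seed=7))


@pytest.fixture
def thomas_cloud():
    """Clustered cloud: 40 parents, sigma = 50 nm offspring."""
    return generate(
        SyntheticSpec(kind="thomas", n_points=2000, box=(1000, 1000, 1000), seed=8,
                      params={"n_parents": 40, "sigma": 50.0})
    )


@pytest.fixture
def two_blob_cloud():
    """Two tight 50-point blobs (diameter ~40 nm) separated by 600 nm."""
    r = np.random.default_rng(3)
    a = r.uniform(0, 40, size=(50, 3))
    b = r.uniform(0, 40, size=(50, 3)) + [600.0, 0.0, 0.0]
    return LocalizationCloud(np.vstack([a, b]))
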