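import numpy as np
import pytest

from camloc.synthetic import LesionSpec, default_specs, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """200 images, 64 px, 3 geometric lesion classes (shared, read-only)."""
    return generate_dataset(200, 64, default_specs(3),
                            background_noise_sd=0.05,
                            no_finding_fraction=0.25, seed=7)


@pytest.fixture()
def disk_only_dataset():
    """200 images with a single disk class of known size range."""
    spec = LesionSpec(0, "disk", intensity=0.6, size_range=(10, 16))
    return generate_dataset(200, 64, [spec], background_noise_sd=0.05,
                            no_finding_fraction=0.3, seed=11)
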