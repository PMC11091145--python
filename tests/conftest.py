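import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from msiflux import msi, synthetic  # noqa: E402


@pytest.fixture(scope="session")
def sim():
    """Mid-size glutamine-tracer dataset at the default noise conditions."""
    return synthetic.simulate_dataset(width=48, height=48, n_types=3, seed=11)


@pytest.fixture(scope="session")
def sim_clean():
    """Noiseless, TIC-flat dataset: every pixel of a phenotype is identical."""
    return synthetic.simulate_dataset(
        width=24, height=24, n_types=3, seed=5, noise_sd=0.0, tic_cv=0.0
    )


@pytest.fixture(scope="session")
def normalized(sim):
    image, _ = msi.tic_normalize(sim.image)
    return image


@pytest.fixture()
def toy_image():
    return msi.SpectralImage(
        coords=np.array([[0, 0], [0, 1], [1, 0]]),
        mz=np.array([100.0, 200.0, 300.0]),
        intensities=np.array([[2.0, 3.0, 5.0], [1.0, 1.0, 2.0], [0.0, 4.0, 4.0]]),
    )
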