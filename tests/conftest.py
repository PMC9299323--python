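import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ctqa

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle() -> ctqa.PhantomBundle:
    """One default phantom (sigma 10 HU white noise) shared across tests."""
    return ctqa.generate_phantom(ctqa.PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def analyzed(default_bundle):
    """The default phantom with its eroded mask, SCF map and partition."""
    eroded = ctqa.erode_mask(default_bundle.organ_mask)
    scf = ctqa.compute_scf_map(default_bundle.image, eroded)
    part = ctqa.partition_regions(scf, eroded)
    return default_bundle, eroded, scf, part


def make_image(pixels, spacing=(1.0, 1.0), ident="test"):
    return ctqa.CTImage(np.asarray(pixels, dtype=float), spacing[0], spacing[1], ident)


@pytest.fixture
def flat_image():
    return make_image(np.full((32, 32), 50.0))
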