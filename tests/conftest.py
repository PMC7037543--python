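import numpy as np
import pytest

from lcmap import PhantomSpec, build_phantom
from lcmap.pipeline import segment_subject


def small_phantom_spec() -> PhantomSpec:
    """A reduced-FOV phantom for fast smoke tests (same tube geometry)."""
    return PhantomSpec(
        grid_shape=(64, 64, 48),
        brainstem_semiaxes_mm=(10.0, 11.0, 10.0),
        distractor_blobs=[],
    )


@pytest.fixture(scope="session")
def phantom():
    """Default-condition phantom, fixed seed, shared across the suite."""
    return build_phantom(PhantomSpec(), seed=7)


@pytest.fixture(scope="session")
def pipeline_result(phantom):
    """End-to-end segmentation of the default phantom (default config)."""
    return segment_subject(phantom.mt, phantom.nomt, phantom.truth_ventricle,
                           phantom.truth_brainstem)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
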