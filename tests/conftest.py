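import numpy as np
import pytest

from coronal_caps.cohort import CohortSpec, PhantomParams, render_phantom

# desk-scale volume for tests: structures comfortably contained, fast to render
SMALL_SHAPE = (64, 72, 64)


def small_params(**kw) -> PhantomParams:
    return PhantomParams(volume_shape=SMALL_SHAPE, **kw)


@pytest.fixture(scope="session")
def clean_phantom():
    """One default phantom reused across read-only tests."""
    return render_phantom(small_params(), seed=3)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return render_phantom(small_params(noise_sd=0.0), seed=3)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort (12 patients) shared by split/pipeline-adjacent tests."""
    from coronal_caps.cohort import generate_cohort

    spec = CohortSpec(n_patients=12, seed=5, base_params=small_params())
    return generate_cohort(spec)
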