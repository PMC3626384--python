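import numpy as np
import pytest

from heliovent.phantom import end_to_end_fixture


@pytest.fixture(scope="session")
def easy_run():
    """Easy-preset phantom processed once by the full pipeline."""
    from heliovent.pipeline import run_pipeline_arrays

    phantom, specs = end_to_end_fixture("easy")
    result = run_pipeline_arrays(phantom.image, specs)
    return phantom, specs, result


@pytest.fixture(scope="session")
def realistic_run():
    from heliovent.pipeline import run_pipeline_arrays

    phantom, specs = end_to_end_fixture("realistic")
    result = run_pipeline_arrays(phantom.image, specs)
    return phantom, specs, result


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
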