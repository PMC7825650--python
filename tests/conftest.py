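import numpy as np
import pytest

from pgxcombine import make_worked_example_cohort, run_pipeline


@pytest.fixture(scope="session")
def worked_example_cohort():
    """The deterministic 614-subject worked-example cohort."""
    return make_worked_example_cohort(seed=1)


@pytest.fixture(scope="session")
def worked_example_result(worked_example_cohort):
    """Full pipeline output on the worked-example cohort (computed once)."""
    fx = worked_example_cohort
    return run_pipeline(fx.genotypes, fx.probe_tracks, fx.regions, fx.definitions)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
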