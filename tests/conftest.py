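import numpy as np
import pytest

from restband import pipeline, simulate


@pytest.fixture(scope="session")
def small_cohort_spec():
    """A reduced recording geometry that keeps time-domain tests fast."""
    return simulate.CohortSpec(
        n_young=3, n_older=3, n_channels=2, segment_len=20.0,
        n_segments_per_condition=1, seed=42,
    )


@pytest.fixture(scope="session")
def study_analysis():
    """One full fast-path analysis at the study's cohort shape."""
    cfg = pipeline.RunConfig(eeg_mode="spectrum", cohort=simulate.CohortSpec(seed=7))
    return pipeline.analyze_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
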