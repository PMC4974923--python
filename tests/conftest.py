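import numpy as np
import pytest

import emogait as eg


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects x 2 sites x 3 emotions, one minute each (300 samples at 5 Hz)."""
    return eg.generate_cohort(eg.CohortConfig(n_subjects=6, seed=11))


@pytest.fixture(scope="session")
def feature_table(small_cohort):
    """Per-segment features of the small cohort under the w=3 filter."""
    return eg.build_feature_table(small_cohort, eg.FilterConfig(3))


def make_recording(samples, subject="S000", site="wrist", emotion="neutral", rate=5.0):
    return eg.TriaxialRecording(
        subject_id=subject, site=site, emotion=emotion, samples=samples, sampling_rate=rate
    )
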