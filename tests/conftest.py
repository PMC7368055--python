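import numpy as np
import pytest

from thromboflow.imaging import quantify_run, segment_run
from thromboflow.registry import Condition
from thromboflow.synthetic import generate_run_images, profile_for


@pytest.fixture(scope="session")
def tf_condition():
    return Condition(tf=True, tf_dose_pm=500.0)


@pytest.fixture(scope="session")
def m6_run(tf_condition):
    """One synthetic collagen-I + TF flow run (images + ground truth)."""
    profile = profile_for("M6", tf_condition)
    return generate_run_images("M6", tf_condition, profile, seed=7, shape=(192, 192))


@pytest.fixture(scope="session")
def m6_segmented(m6_run):
    run, _ = m6_run
    return segment_run(run)


@pytest.fixture(scope="session")
def m6_quant(m6_run):
    run, _ = m6_run
    return quantify_run(run)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
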