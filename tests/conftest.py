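import numpy as np
import pytest

from ocipipe import synthetic as syn
from ocipipe.tuning import RecordingGeometry


@pytest.fixture(scope="session")
def model():
    return syn.CochlearModel()


@pytest.fixture(scope="session")
def probe():
    return RecordingGeometry()


@pytest.fixture(scope="session")
def layout250():
    """16 emitters at 250 um pitch, inserted to mid-cochlea."""
    return syn.EmitterLayout(pitch_mm=0.25, insertion_depth_mm=3.0)


@pytest.fixture(scope="session")
def act_uniform():
    """Activation model with full, uniform opsin transduction."""
    return syn.ActivationModel(transduction_profile=1.0)


@pytest.fixture(scope="session")
def hearing_cohort(model):
    """Small mixed cohort drawn at a fixed seed (2 hearing, 1 deaf)."""
    spec = syn.CohortSpec(3, ("hearing", "hearing", "deaf"), seed=7)
    return syn.draw_cohort(spec, model)


def poisson_spike_train(rng, rate_hz, t0_ms, t1_ms):
    n = rng.poisson(rate_hz * (t1_ms - t0_ms) * 1e-3)
    return np.sort(rng.uniform(t0_ms, t1_ms, n))
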