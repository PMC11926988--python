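import numpy as np
import pytest

from dualsurv import Cohort, PatientRecord, RunConfig, SimParams, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def tiny_cohort():
    """Two-patient cohort with hand-sized bags."""
    rng = np.random.default_rng(7)
    recs = [
        PatientRecord("pt-a", rng.normal(size=(3, 768)).astype(np.float32),
                      rng.normal(size=(2, 256)).astype(np.float32),
                      time=12.5, censor=0),
        PatientRecord("pt-b", rng.normal(size=(1, 768)).astype(np.float32),
                      rng.normal(size=(1, 256)).astype(np.float32),
                      time=40.0, censor=1),
    ]
    return Cohort(records=recs).validate()


@pytest.fixture
def small_sim_cohort():
    """Light synthetic cohort (small bags) for training smoke tests."""
    params = SimParams(n_patients=60, patch_range=(6, 12), pathway_count=8,
                       informative_pathway_count=4, seed=3)
    cohort, truth = generate_cohort(params)
    return cohort, truth


@pytest.fixture
def toy_config():
    return RunConfig(d_model=16, d_state=4, conv_width=2, seed=0)
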