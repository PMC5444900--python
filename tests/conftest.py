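import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from swimsort import (
    CellSimConfig,
    GTEvent,
    LearnerModel,
    SessionConfig,
    TrialProtocol,
    simulate_session,
    simulate_trace,
)


@pytest.fixture
def quiet_cell():
    """A cell with no spontaneous activity and no recording noise."""
    return CellSimConfig(basal_complex_rate=0.0, basal_simple_rate=0.0,
                         basal_pf_rate=0.0, noise_sd=0.0)


@pytest.fixture
def noisy_quiet_cell():
    """No spontaneous activity, default recording noise."""
    return CellSimConfig(basal_complex_rate=0.0, basal_simple_rate=0.0,
                         basal_pf_rate=0.0, noise_sd=0.2)


@pytest.fixture
def short_protocol():
    return TrialProtocol(1, "us_alone", us_time=0.8, sweep_duration=1.0)


@pytest.fixture
def single_cf_trace(noisy_quiet_cell, short_protocol):
    trace, truth = simulate_trace(
        noisy_quiet_cell, short_protocol, seed=1,
        extra_events=[GTEvent(0.5, "complex", 4.86)])
    return trace, truth


@pytest.fixture(scope="session")
def small_session_bundle():
    """A 6-trial learner session used by io/pipeline tests."""
    cfg = SessionConfig(
        cell=CellSimConfig(class_label="MCS"),
        learner=LearnerModel(acquisition_trial=2, plateau_cr_prob=0.9),
        n_paired=6, cs_onset=1.5, cs_duration=1.0, post_us=1.0)
    return simulate_session(cfg, seed=7)
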