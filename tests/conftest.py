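import numpy as np
import pytest

import seegamma as sg


@pytest.fixture(scope="session")
def truth():
    return sg.GroundTruth()


@pytest.fixture(scope="session")
def session_trials(truth):
    """One standard 4-block session with behavior filled in."""
    tt = sg.generate_trial_table(4, 225.0, seed=11)
    return sg.generate_behavior(tt, truth, seed=12)


@pytest.fixture(scope="session")
def long_trials(session_trials):
    return [t for t in session_trials if t.length == "long"]


@pytest.fixture(scope="session")
def actor_long_trials(long_trials):
    return [t for t in long_trials if t.task == "actor"]


def lead_traces(lead_class, trials, truth, *, bin_ms=25.0, seed=0, **kw):
    return sg.generate_lead_timecourses(lead_class, trials, truth,
                                        bin_ms=bin_ms, seed=seed, **kw)


@pytest.fixture(scope="session")
def noiseless_truth():
    return sg.GroundTruth(white_noise_sd=0.0, slow_noise_sd=0.0,
                          amplitude_jitter_sd=0.0, onset_jitter_sd_ms=0.0,
                          duration_jitter_sd_ms=0.0)
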