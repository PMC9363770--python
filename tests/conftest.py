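import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phasetag import NoiseModel, StimulusSchedule, TrialSet
from phasetag.synth import simulate_trials

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def schedule():
    """Full-rate schedule matching the emulated experiment."""
    return StimulusSchedule()


@pytest.fixture
def schedule_fast():
    """Reduced sampling rate for tests whose contract does not pin fs."""
    return StimulusSchedule(fs=250.0)


@pytest.fixture
def quiet_noise():
    return NoiseModel(white_sd=0.0, pink_sd=0.0, mains_amp=0.0)


def make_trialset(data, fs, onset, condition="c", participant="p"):
    data = np.atleast_2d(data)
    return TrialSet(
        data=data,
        fs=fs,
        onset_index=onset,
        conditions=np.full(data.shape[0], condition),
        participant_ids=np.full(data.shape[0], participant),
        good_flags=np.ones(data.shape[0], bool),
    )


def synth_trialset(n, schedule, response, noise, perturbations=(), seed=0, latency=0.0):
    data, onset = simulate_trials(
        n, schedule, response, noise, perturbations, rng=seed, latency_offset=latency
    )
    return make_trialset(data, schedule.fs, onset)
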