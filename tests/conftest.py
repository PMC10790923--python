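import numpy as np
import pytest

from nirspain.preprocess import process_recording
from nirspain.synth import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def hard_pain_session(default_config):
    """One simulated Hard-demand game+pain session with its ground truth."""
    return simulate_session(default_config, 0, "hard_pain")


@pytest.fixture(scope="session")
def processed_hard_pain(hard_pain_session):
    rec, _gt = hard_pain_session
    return process_recording(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_recording(rng, duration_s=6.0, condition="easy", quantise=True,
                   with_hr=True, with_ecg=False):
    """A small random but valid SessionRecording for I/O tests."""
    from nirspain.session import SessionRecording

    n = int(duration_s * 10)
    od = rng.normal(0.0, 0.01, size=(8, 2, n))
    accel = rng.normal(0.0, 0.02, size=(3, int(duration_s * 512)))
    accel[2] += 1.0
    hr = rng.normal(70.0, 3.0, size=n) if with_hr else None
    ecg = rng.normal(0.0, 0.1, size=int(duration_s * 250)) if with_ecg else None
    if quantise:
        od = np.round(od, 6)
        accel = np.round(accel, 6)
        if hr is not None:
            hr = np.round(hr, 6)
        if ecg is not None:
            ecg = np.round(ecg, 6)
    return SessionRecording(
        participant_id="P99",
        condition=condition,
        fnirs_od=od,
        accel=accel,
        events=[("baseline", 0.0, duration_s)],
        hr=hr,
        ecg=ecg,
    )
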