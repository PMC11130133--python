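import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mspipe.simulate import (
    GroundTruthUnit,
    StimProtocol,
    biphasic_template,
    make_session,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol() -> StimProtocol:
    """10 Hz / 20 ms pulse train starting after a 60 s baseline."""
    return StimProtocol(epoch_onsets=(60.0,), epoch_durations=(50.0,))


@pytest.fixture(scope="session")
def two_unit_session():
    """60 s wideband session with two well-separated MSN-like templates
    (SNR 6 and 5) on unit-SD noise, plus its ground truth."""
    u1 = GroundTruthUnit(
        "a",
        subtype="D1",
        base_rate=4.0,
        waveform_template=biphasic_template(trough_to_peak_us=400.0, amplitude=6.0),
    )
    u2 = GroundTruthUnit(
        "b",
        subtype="D2",
        base_rate=5.0,
        waveform_template=biphasic_template(
            trough_to_peak_us=600.0, amplitude=5.0, post_peak_frac=0.7, pre_peak_frac=0.15
        ),
    )
    return make_session([u1, u2], None, None, duration=60.0, noise_sd=1.0, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
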