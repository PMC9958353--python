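import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def lujan_slow():
    """1 cm displacement at 12 bpm (tau = 5 s)."""
    from dts4d import LujanParams

    return LujanParams(b=10.0, tau=5.0)


@pytest.fixture
def lujan_fast():
    """4 cm displacement at 25 bpm (tau = 2.4 s) — the most demanding grid corner."""
    from dts4d import LujanParams

    return LujanParams(b=40.0, tau=2.4)


@pytest.fixture
def ramp_waveform():
    """Linear 2 mm/s ramp sampled at 0.033 s: the estimator must recover the slope exactly."""
    from dts4d import RespiratoryWaveform

    t = np.arange(200) * 0.033
    return RespiratoryWaveform(times=t, displacements=2.0 * t, source_label="ramp")
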