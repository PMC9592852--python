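import numpy as np
import pytest

from reachvigor import design as dz
from reachvigor import synth_motion as sm

PX_TO_CM = dz.ScreenGeometry().px_to_cm


@pytest.fixture(scope="session")
def px_to_cm():
    return PX_TO_CM


@pytest.fixture(scope="session")
def noiseless_params():
    """Deterministic motion parameters: no noise, no anomalies, fixed latency."""
    return sm.MotionParams(
        endpoint_noise_sd_cm=0.0,
        path_noise_sd_cm=0.0,
        rt_sd_ms=0.0,
        anomaly_rate=0.0,
        cs_plus_vigor_gain=0.0,
        px_to_cm=PX_TO_CM,
    )


@pytest.fixture(scope="session")
def reaching_schedule():
    return dz.generate_reaching_schedule(1, seed=11, phase="test_safety")


@pytest.fixture(scope="session")
def pavlovian_schedule():
    return dz.generate_pavlovian_schedule(9, 7, seed=11)
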