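import numpy as np
import pytest

from edanx.decompose import BatemanParams, bateman_kernel

FS = 51.2


def make_trace(
    schedule,
    duration=120.0,
    tonic_base=5.0,
    noise_sd=0.0,
    drift_sd=0.0,
    seed=0,
    fs=FS,
):
    """Forward-simulate a conductance trace: tonic + sum of Bateman SCRs."""
    n = int(duration * fs)
    rng = np.random.default_rng(seed)
    kernel = bateman_kernel(BatemanParams(), fs)
    tonic = np.full(n, tonic_base)
    if drift_sd:
        tonic = tonic + np.cumsum(rng.normal(0, drift_sd / np.sqrt(fs), n))
    gsr = tonic.copy()
    for onset, amp in schedule:
        i = int(onset * fs)
        span = min(kernel.size, n - i)
        gsr[i : i + span] += amp * kernel[:span]
    if noise_sd:
        gsr = gsr + rng.normal(0, noise_sd, n)
    return gsr


@pytest.fixture
def fs():
    return FS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
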