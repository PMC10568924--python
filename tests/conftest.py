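import numpy as np
import pytest

from usvkit.spectral import AudioRecording, StftParams
from usvkit.synthetic import CallSpec, RecordingPlan, synth_recording


@pytest.fixture(scope="session")
def stft_params() -> StftParams:
    return StftParams()


@pytest.fixture(scope="session")
def trill_recording():
    """One 40 ms trill at ~20 dB in-band SNR over tilted noise (0.5 s)."""
    call = CallSpec(
        "trill", f0=55_000.0, fm_depth=4_000.0, fm_rate=60.0,
        duration_s=0.040, amplitude=0.05, onset_s=0.2,
        jitter_hz=300.0, jitter_seed=7,
    )
    plan = RecordingPlan(duration_s=0.5, noise_sigma=0.002, calls=(call,), seed=11)
    return synth_recording(plan)


@pytest.fixture(scope="session")
def silence_recording() -> AudioRecording:
    return AudioRecording(np.zeros(125_000), 250_000.0, id="silence")
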