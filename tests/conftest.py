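import numpy as np
import pytest

from mwnetdyn import BANDS, BandedRecording, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(
    data: np.ndarray,
    rate: float = 256.0,
    band: str | None = None,
    participant_id: str = "P01",
    trial_label: str = "FL-1",
) -> Recording:
    names = [f"ch{i}" for i in range(data.shape[0])]
    if band is None:
        return Recording(participant_id, trial_label, rate, names, data)
    return BandedRecording(
        participant_id, trial_label, rate, names, data,
        band=band, band_edges=BANDS[band],
    )


@pytest.fixture
def noise_banded(rng):
    """4 s of independent 8-channel noise tagged as alpha band."""
    data = rng.standard_normal((8, 1024)) * 10
    return make_recording(data, band="alpha")
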