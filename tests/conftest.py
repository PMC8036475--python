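import numpy as np
import pytest

from accmet.signal_processing import IntensitySeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_intensity(values, epoch_length=60.0, position="hip", participant_id="p1", start=0.0):
    values = np.asarray(values, dtype=float)
    return IntensitySeries(
        participant_id=participant_id,
        position=position,
        epoch_start=start + epoch_length * np.arange(values.size),
        epoch_length=epoch_length,
        intensity=values,
    )


@pytest.fixture
def intensity_factory():
    return make_intensity
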