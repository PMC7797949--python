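import numpy as np
import pytest

from evcoloc import (
    AcquisitionParams,
    ChannelTransform,
    PopulationSpec,
    Spot,
)

CHANNELS = ("CD9", "CD63", "CD81")

# tetraspanin mix of a heterogeneous EV sample: CD63 singles and CD9·CD81
# doubles dominate, ~11% triple-positive, minor remaining classes
HEK_FRACTIONS = {
    "CD63": 0.34,
    "CD9∙CD81": 0.34,
    "CD9∙CD63∙CD81": 0.11,
    "CD9": 0.09,
    "CD81": 0.08,
    "CD9∙CD63": 0.02,
    "CD63∙CD81": 0.02,
}


def make_params(shifts=None, **kwargs) -> AcquisitionParams:
    """AcquisitionParams for CHANNELS with optional per-channel (dx, dy) shifts."""
    shifts = shifts or {}
    transforms = {
        c: ChannelTransform.translation(*shifts[c])
        if c in shifts
        else ChannelTransform.identity()
        for c in CHANNELS
    }
    return AcquisitionParams(channel_transforms=transforms, **kwargs)


def make_spot(x, y, channel="CD9", intensity=1000.0, sigma=1.5, snr=20.0) -> Spot:
    return Spot(
        channel=channel, x=float(x), y=float(y), intensity=intensity,
        sigma=sigma, background=100.0, fit_rss=0.0, snr=snr,
    )


@pytest.fixture
def channels():
    return CHANNELS


@pytest.fixture
def hek_spec():
    params = make_params()
    return PopulationSpec(
        channels=CHANNELS,
        class_fractions=HEK_FRACTIONS,
        n_vesicles=300,
        brightness_mean=params.brightness_for_snr(12.0),
    )


@pytest.fixture
def default_params():
    return make_params()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
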