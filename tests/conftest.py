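import numpy as np
import pytest

from shakerval import (
    DeviceSpec,
    MountingOrientation,
    ShakerConfig,
    build_validity_protocol,
)


@pytest.fixture(scope="session")
def cfg():
    return ShakerConfig()


@pytest.fixture(scope="session")
def validity_protocol(cfg):
    return build_validity_protocol(cfg)


def noiseless_spec(device_id="ideal", sampling_hz=100.0, mounting=None, **kw):
    """A clean device: no noise, unit gain, zero bias, no dropout."""
    kw.setdefault("noise_sd_g", 0.0)
    return DeviceSpec(
        device_id=device_id,
        sampling_hz=sampling_hz,
        mounting=mounting or MountingOrientation.gravity_in_plane(),
        **kw,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
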