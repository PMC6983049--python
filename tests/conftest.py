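import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fabricmotion.orientation import RotationSpec
from fabricmotion.synthetic_data import (
    ClothingChannelParams,
    SynthConfig,
    generate_sensor_pair,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def canonical_pair():
    """Walking pair with the canonical clothing distortions.

    38-sample lag (0.76 s at 50 Hz), 15 deg tilt about x, 1.1 amplitude
    scaling, no swing, low noise — the go-to fixture for alignment and
    variant checks.
    """
    cfg = SynthConfig(
        schedule=(("standing", 10.0), ("walking", 60.0)),
        noise_sd=0.02,
        seed=7,
    )
    params = ClothingChannelParams(
        lag_samples=38,
        rotation=RotationSpec(np.array([1.0, 0.0, 0.0]), np.radians(15.0)),
        swing_amp=0.0,
        amp_scale=1.1,
        noise_sd=0.02,
    )
    pair, log, truth = generate_sensor_pair(cfg, params)
    return pair, log, truth


@pytest.fixture(scope="session")
def clean_day():
    """Noise-light synthetic day covering all four classifier classes."""
    cfg = SynthConfig(
        schedule=(
            ("standing", 60.0),
            ("walking", 90.0),
            ("sitting", 90.0),
            ("running", 60.0),
            ("standing", 30.0),
            ("sitting", 60.0),
        ),
        noise_sd=0.01,
        seed=11,
    )
    from fabricmotion.synthetic_data import generate_body_stream

    series, log = generate_body_stream(cfg)
    return cfg, series, log
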