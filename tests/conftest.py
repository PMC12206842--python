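import numpy as np
import pytest

from tedeye.types import Calibration, PathologyParams, default_geometry


@pytest.fixture(scope="session")
def geom():
    return default_geometry()


@pytest.fixture(scope="session")
def calib():
    return Calibration.from_mm_per_px(0.1)


@pytest.fixture(scope="session")
def healthy_eye(geom):
    from tedeye.synthetic import generate_eye

    return generate_eye(geom, PathologyParams(), seed=42)


@pytest.fixture(scope="session")
def retraction_eye(geom):
    from tedeye.synthetic import generate_eye

    return generate_eye(
        geom, PathologyParams(upper_retraction_mm=2.0), seed=42
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
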