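import numpy as np
import pytest

from cyanovia import AssayConfig, CalibratedField


@pytest.fixture
def config() -> AssayConfig:
    return AssayConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


def make_field(pixels: np.ndarray, um_per_px: float = 0.5, field_id: str = "f") -> CalibratedField:
    return CalibratedField(field_id=field_id, pixels=pixels, um_per_px=um_per_px)


@pytest.fixture
def random_field(rng) -> CalibratedField:
    px = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
    return make_field(px)
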