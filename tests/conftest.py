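import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # test-local oracle modules

from fractalperf.phantom import PhantomConfig, make_phantom


def small_config(**overrides) -> PhantomConfig:
    """Small, fast phantom grid for unit tests (LV geometry derived)."""
    kw = dict(
        shape=(32, 32, 12),
        spacing_mm=(2.0, 2.0, 3.0),
        r_out_mm=None,
        wall_mm=None,
        n_frames=16,
        seed=0,
    )
    kw.update(overrides)
    return PhantomConfig(**kw)


@pytest.fixture(scope="session")
def small_study():
    """Default-pattern small phantom (all territories normal)."""
    return make_phantom(small_config())


@pytest.fixture(scope="session")
def mixed_study():
    """Full-size calibrated phantom with one territory per ischemia class."""
    return make_phantom(
        PhantomConfig(
            n_frames=12,
            territory_pattern={
                "LAD": "obstructive", "LCX": "microvascular", "RCA": "none"
            },
            seed=7,
        )
    )
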