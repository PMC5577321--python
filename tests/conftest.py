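import numpy as np
import pytest

import stromap as sm

#: Small, fast phantom conditions used by unit tests (the generator's
#: defaults describe a full-size section and are exercised in the
#: acceptance suite).
SMALL = dict(
    image_size_px=(512, 512),
    pixel_size_um=2.0,
    n_sites=2,
    min_site_separation_mm=0.4,
    roi_side_mm=0.5,
    needle_track_diameter_um=0.0,  # phantoms render no physical track
    seed=11,
)


def small_config(**overrides) -> sm.PhantomConfig:
    return sm.PhantomConfig(**{**SMALL, **overrides})


@pytest.fixture(scope="session")
def small_phantom() -> sm.Phantom:
    return sm.generate_phantom(small_config())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
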