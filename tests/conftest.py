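import numpy as np
import pytest

import vhqpi as v


@pytest.fixture(scope="session")
def phantom_t20():
    """Seeded 512^2 RBC interferogram, carrier period 20 px, noise 0.05."""
    spec = v.SyntheticSpec(size=512, period=20.0, noise_amp=0.05, background="gaussian", seed=1)
    phase = v.rbc_phase(512, spec)
    intensity, model = v.generate_interferogram(spec, phase)
    return spec, phase, intensity, model


@pytest.fixture(scope="session")
def decomposition_t20(phantom_t20):
    _, _, intensity, _ = phantom_t20
    return v.uvid_filter(intensity)


@pytest.fixture(scope="session")
def interior512():
    return v.interior_mask((512, 512), border=16, exclude_disk=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def carrier(n: int, period: float, axis: str = "x") -> np.ndarray:
    """Pure cosine carrier raster."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    c = xx if axis == "x" else yy
    return np.cos(2 * np.pi * c / period)
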