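import numpy as np
import pytest

from reharm.phantom import (
    GaussianBump,
    PhantomSpec,
    TimepointDistortion,
    generate_subject,
)


@pytest.fixture(scope="session")
def zero_noise_subject():
    """Undistorted zero-noise phantom on a small grid (cheap shared fixture)."""
    spec = PhantomSpec(noise_sd=0.0, seed=11).scaled((48, 48, 24))
    return generate_subject(spec, 2)[0]


@pytest.fixture(scope="session")
def native_zero_subject():
    """Undistorted zero-noise phantom at the native 96x96x48 grid."""
    spec = PhantomSpec(noise_sd=0.0, seed=11)
    return generate_subject(spec, 2)[0]


@pytest.fixture(scope="session")
def distorted_pair():
    """Reference + distorted follow-up with known rigid/deformable/intensity truth."""
    spec = PhantomSpec(
        noise_sd=10.0,
        seed=5,
        distortions=[
            TimepointDistortion(
                gain=1.2,
                offset=10.0,
                translation=(4.0, -2.0, 0.0),
                rotation_deg=2.0,
                bumps=[GaussianBump((48, 55, 48), 18.0, (3.0, 2.0, -1.0))],
            )
        ],
    ).scaled((64, 64, 32))
    tps = generate_subject(spec, 2)
    return tps[0], tps[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
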