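import numpy as np
import pytest

from tieredpol import (
    DichroicAbsorption,
    OpponentConfig,
    OpponentModel,
    TieredPairGeometry,
)


@pytest.fixture(scope="session")
def dichroic() -> DichroicAbsorption:
    """Blowfly DRA values: k = 0.0075 um^-1, dichroic ratio 10, peak 335 nm."""
    return DichroicAbsorption()


@pytest.fixture(scope="session")
def pair_equal() -> TieredPairGeometry:
    """The 100 um dorsal-rim CRP split equally between R7 and R8."""
    return TieredPairGeometry(100.0, 0.5)


@pytest.fixture(scope="session")
def theta_grid() -> np.ndarray:
    return np.linspace(0.0, 90.0, 181)


def make_opponent(
    dichroic,
    l=100.0,
    frac=0.5,
    ni=1e5,
    d=0.1,
    sigma_in_sq=5e-5,
    tau_ms=90.0,
    saturation=False,
) -> OpponentModel:
    return OpponentModel(
        TieredPairGeometry(l, frac),
        dichroic,
        OpponentConfig(ni, d, sigma_in_sq, tau_ms, saturation),
    )
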