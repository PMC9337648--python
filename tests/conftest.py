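import numpy as np
import pytest

from thyrus.acquisition import AcquisitionParams, ObserverProfile, simulate_sweep
from thyrus.phantom import LobePhantom


@pytest.fixture(scope="session")
def ellipsoid_phantom() -> LobePhantom:
    """Plain ellipsoid lobe (a,b,c) = (8,6,12) mm with exact volume known."""
    return LobePhantom((8.0, 6.0, 12.0)).with_true_volume(0.1)


@pytest.fixture(scope="session")
def noiseless_observer() -> ObserverProfile:
    return ObserverProfile("MD0", (1.0, 1.0, 1.0), (0.0, 0.0, 0.0),
                           sweep_speed=12.0, pose_noise_scale=0.0)


@pytest.fixture(scope="session")
def clean_params() -> AcquisitionParams:
    """Small noise-free acquisition: no speckle, no wobble, no texture."""
    return AcquisitionParams.desk(image_px=64, pixel_mm=0.4, frame_rate=24.0,
                                  speckle=False, texture_amp=0.0,
                                  wobble_deg=0.0, wobble_mm=0.0)


@pytest.fixture(scope="session")
def clean_sweep(ellipsoid_phantom, noiseless_observer, clean_params):
    return simulate_sweep(ellipsoid_phantom, noiseless_observer, clean_params, seed=11)
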