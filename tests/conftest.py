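import numpy as np
import pytest

from dazzlesim import glare, spots


@pytest.fixture
def observer():
    return glare.ObserverProfile(age=30, pigmentation=0.5)


@pytest.fixture
def scene():
    # reference indoor scene: mid ambient, high-contrast 2.75 deg target
    return glare.SceneConditions(
        ambient_luminance=13.14, target_contrast=0.89, target_angular_size=2.75
    )


@pytest.fixture
def exposure():
    return glare.LaserExposure(
        wavelength=532.0, eye_irradiance=1.537, incidence_angle=0.5
    )


@pytest.fixture
def defected_spot_factory():
    """Seeded generator of notched, noisy Gaussian spots with ground truth."""

    def make(seed: int, shape=(96, 96)):
        truth = spots.GaussianSpotModel(
            amplitude=1.0,
            center=(40 + 0.3 * (seed % 5), 44 - 0.4 * (seed % 3)),
            sigmas=(8.0, 8.0),
        )
        image, record = spots.generate_synthetic_spot(
            truth,
            shape=shape,
            defects={"notch": {"angle_deg": 20 + 13 * seed, "width_deg": 45,
                               "depth": 0.7}},
            noise_sigma=0.01,
            seed=seed,
        )
        return image, truth, record

    return make


@pytest.fixture
def disc_image():
    yy, xx = np.mgrid[0:64, 0:64]
    return (((xx - 32.0) ** 2 + (yy - 32.0) ** 2) <= 20.0**2).astype(float)
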