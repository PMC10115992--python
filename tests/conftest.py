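import numpy as np
import pytest

from aceval import ImageVolume, Mask, LesionSpec, PhantomSpec, make_phantom


def centered_volume(data, spacing=(1.0, 1.0, 1.0)):
    """ImageVolume whose physical origin sits at the grid centre."""
    shape = data.shape[:3]
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    return ImageVolume(data=data, spacing=spacing, origin=origin)


def sphere_data(shape, spacing, center_mm, radius_mm):
    vol = centered_volume(np.zeros(shape), spacing)
    x, y, z = vol.coordinate_grids()
    cx, cy, cz = center_mm
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= radius_mm ** 2


@pytest.fixture(scope="session")
def noiseless_phantom():
    """64^3 @ 3 mm head with one 12-mm lesion of TBR 2.5 and no noise."""
    spec = PhantomSpec(shape=(64, 64, 64), spacing=(3.0, 3.0, 3.0),
                       lesions=[LesionSpec(center_mm=(28.0, 12.0, 8.0),
                                           radius_mm=12.0, tbr=2.5)],
                       noise_sigma_frac=0.0, seed=11)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(shape=(64, 64, 64), spacing=(3.0, 3.0, 3.0),
                       lesions=[LesionSpec(center_mm=(28.0, 12.0, 8.0),
                                           radius_mm=12.0, tbr=2.5)],
                       noise_sigma_frac=0.05, seed=11)
    return make_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def as_mask(vol_or_data, spacing=(1.0, 1.0, 1.0), label="mask"):
    if isinstance(vol_or_data, ImageVolume):
        return Mask(data=vol_or_data.data, spacing=vol_or_data.spacing,
                    origin=vol_or_data.origin, label=label)
    data = np.asarray(vol_or_data)
    shape = data.shape
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    return Mask(data=data, spacing=spacing, origin=origin, label=label)
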