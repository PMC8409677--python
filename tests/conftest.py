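import numpy as np
import pytest

from melissoscope import phantoms
from melissoscope.stackio import FocalStack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def disc_mask(radius: int, pad: int = 4) -> np.ndarray:
    size = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[:size, :size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2


@pytest.fixture
def brassica_bf():
    return phantoms.appearance_from_book("Brassica", "BF")


@pytest.fixture
def tiny_stack():
    """5-plane 64x64 stack with a textured square sharp in plane 2."""
    rng = np.random.default_rng(7)
    base = np.full((64, 64, 3), 180, np.uint8)
    base[20:44, 20:44] = rng.integers(40, 120, (24, 24, 3)).astype(np.uint8)
    planes = []
    from scipy import ndimage as ndi
    for k in range(5):
        sigma = abs(k - 2) * 1.5
        if sigma:
            img = np.stack([ndi.gaussian_filter(base[..., c].astype(float), sigma)
                            for c in range(3)], axis=-1)
            planes.append(np.clip(img, 0, 255).astype(np.uint8))
        else:
            planes.append(base)
    return FocalStack(planes=np.stack(planes), pixel_size=0.5,
                      plane_spacing=8.0, modality="BF")
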